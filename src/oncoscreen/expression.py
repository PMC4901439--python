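"""Differential-expression screen for count data.

The candidate screen starts from gene-level read counts in two tumor
contexts (bulk tumor vs. normal tissue, and stem-cell lines vs. normal
progenitors).  Each context is tested with a negative-binomial model and
gated at an adjusted p-value and a log2 fold-change threshold; the two
upregulated sets are then intersected and the overlap assessed with an
upper-tail hypergeometric test against the RNA-binding-protein universe.

The module also carries two small utilities used elsewhere in the screen:
a Wilcoxon rank-sum group comparison (tumor-grade trend) and the
2^-ddCt relative-expression formula for qPCR knockdown validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "GeneSet",
    "RBP_UNIVERSE_SIZE",
    "estimate_size_factors",
    "differential_expression",
    "benjamini_hochberg",
    "apply_de_gates",
    "overlap_test",
    "group_expression_comparison",
    "ddct_relative_expression",
]

#: Size of the curated human RNA-binding-protein catalog used as the
#: default universe for overlap tests.
RBP_UNIVERSE_SIZE = 1542


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label required per sample")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DEResult:
    """Per-gene differential-expression call."""

    gene_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    direction: str = "none"  # up | down | none
    tested: bool = True


@dataclass
class GeneSet:
    """Named gene set inside a finite universe."""

    name: str
    members: set[str] = field(default_factory=set)
    universe_size: int = RBP_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if len(self.members) > self.universe_size:
            raise ValueError(
                f"gene set {self.name!r} has {len(self.members)} members but "
                f"universe size is only {self.universe_size}"
            )

    def __len__(self) -> int:
        return len(self.members)


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors.

    Each sample's factor is the median, over genes with all-positive
    counts, of that sample's count divided by the gene's geometric mean
    across samples.

    Parameters
    ----------
    counts
        Non-negative (n_genes, n_samples) matrix.

    Returns
    -------
    Positive per-sample scale factors.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D gene x sample matrix")
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (consider a pseudo-reference fallback with a pseudocount)"
        )
    ref = counts[all_positive]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1))
    return np.median(ref / geo_mean[:, None], axis=0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values ``min_{j>=i} m * p_(j) / j`` capped at 1,
    in the input order.  NaN inputs are rejected rather than silently
    propagated.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not adjustable")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pooled_dispersion(norm: np.ndarray, groups: tuple[np.ndarray, np.ndarray],
                       inv_s: np.ndarray) -> float:
    """Method-of-moments common dispersion from within-group variability.

    For normalized counts y = K/s with K ~ NB(mu, alpha) the within-group
    variance satisfies E[S^2] ~= mu * mean(1/s) + alpha * mu^2, so each
    gene yields a moment estimate pooled across the two groups; the common
    alpha is the across-gene mean of the per-gene estimates floored at 0.
    Planted between-group effects do not inflate it because only
    within-group variance enters.
    """
    num = 0.0
    den = 0.0
    alphas = []
    for idx in groups:
        y = norm[:, idx]
        n = y.shape[1]
        if n < 2:
            continue
        ybar = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        m_inv = float(np.mean(inv_s[idx]))
        ok = ybar > 0
        a = np.zeros_like(ybar)
        a[ok] = (s2[ok] - ybar[ok] * m_inv) / ybar[ok] ** 2
        alphas.append(np.where(ok, a, np.nan))
    stacked = np.nanmean(np.vstack(alphas), axis=0)
    stacked = stacked[np.isfinite(stacked)]
    if stacked.size == 0:
        return 1e-8
    return max(float(np.mean(np.clip(stacked, 0.0, None))), 1e-8)


def differential_expression(
    counts: CountMatrix,
    contrast: tuple[str, str] | None = None,
    pseudocount: float = 0.5,
    engine: str = "nb_wald",
) -> pd.DataFrame:
    """Two-group differential expression on a count matrix.

    The default engine fits a negative-binomial model with median-of-ratios
    size factors and a single pooled method-of-moments dispersion, and
    tests the log fold change with a Wald statistic against a standard
    normal.  ``engine="log_t"`` instead runs a two-sample t-test on
    log2(normalized count + pseudocount) values, the convention for
    log-intensity platforms.

    Parameters
    ----------
    counts
        Count matrix with exactly two group labels (or a ``contrast``
        naming two of its labels).
    contrast
        ``(reference, treatment)`` pair; log2 fold change is
        treatment over reference.
    pseudocount
        Added to normalized group means for the displayed fold change.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2_fold_change``,
    ``p_value``, ``p_adjusted``, ``direction``, ``tested``.  Genes with
    all-zero counts are reported untested with NaN statistics; BH
    adjustment runs across tested genes only.
    """
    labels = np.asarray(counts.group_labels)
    if contrast is None:
        uniq = counts.groups
        if len(uniq) != 2:
            raise ValueError(
                f"count matrix has groups {uniq}; a two-level contrast is required"
            )
        contrast = (uniq[0], uniq[1])
    ref_label, trt_label = contrast
    idx_ref = np.where(labels == ref_label)[0]
    idx_trt = np.where(labels == trt_label)[0]
    if idx_ref.size < 2 or idx_trt.size < 2:
        raise ValueError("each contrast group needs at least 2 samples")

    mat = np.asarray(counts.counts, dtype=float)
    sf = estimate_size_factors(mat[:, np.concatenate([idx_ref, idx_trt])])
    # re-expand size factors to original sample positions
    sf_full = np.ones(mat.shape[1])
    sf_full[np.concatenate([idx_ref, idx_trt])] = sf
    norm = mat / sf_full[None, :]
    inv_s = 1.0 / sf_full

    tested = mat[:, np.concatenate([idx_ref, idx_trt])].sum(axis=1) > 0

    mean_ref = norm[:, idx_ref].mean(axis=1)
    mean_trt = norm[:, idx_trt].mean(axis=1)
    lfc = np.log2(mean_trt + pseudocount) - np.log2(mean_ref + pseudocount)

    n_ref, n_trt = idx_ref.size, idx_trt.size
    if engine == "nb_wald":
        alpha = _pooled_dispersion(norm, (idx_ref, idx_trt), inv_s)
        m_inv_ref = float(np.mean(inv_s[idx_ref]))
        m_inv_trt = float(np.mean(inv_s[idx_trt]))
        with np.errstate(divide="ignore", invalid="ignore"):
            # delta-method variance of log(group mean) under Var(y) = mu/s + alpha mu^2
            var_ref = m_inv_ref / mean_ref + alpha
            var_trt = m_inv_trt / mean_trt + alpha
            se = np.sqrt(var_ref / n_ref + var_trt / n_trt)
            z = (np.log(mean_trt) - np.log(mean_ref)) / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        # genes observed in only one group: Wald on log means is undefined;
        # fall back to the t engine on logged normalized counts
        degenerate = tested & ((mean_ref == 0) | (mean_trt == 0))
        if np.any(degenerate):
            lref = np.log2(norm[np.ix_(degenerate, idx_ref)] + pseudocount)
            ltrt = np.log2(norm[np.ix_(degenerate, idx_trt)] + pseudocount)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tt = stats.ttest_ind(ltrt, lref, axis=1)
            p[degenerate] = tt.pvalue
    elif engine == "log_t":
        lref = np.log2(norm[:, idx_ref] + pseudocount)
        ltrt = np.log2(norm[:, idx_trt] + pseudocount)
        tt = stats.ttest_ind(ltrt, lref, axis=1)
        p = np.asarray(tt.pvalue)
    else:
        raise ValueError(f"unknown DE engine {engine!r}")

    # constant genes give 0/0 -> NaN; no evidence against the null
    p = np.asarray(p, dtype=float)
    p[tested & ~np.isfinite(p)] = 1.0
    p = np.where(tested, np.clip(p, 0.0, 1.0), np.nan)

    padj = np.full_like(p, np.nan)
    padj[tested] = benjamini_hochberg(p[tested])

    out = pd.DataFrame(
        {
            "log2_fold_change": np.where(tested, lfc, np.nan),
            "p_value": p,
            "p_adjusted": padj,
            "tested": tested,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    out["direction"] = "none"
    return out


def apply_de_gates(
    de_results: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05,
    universe_size: int | None = None,
) -> tuple[GeneSet, GeneSet]:
    """Partition DE results into up/down sets at the screen's gates.

    A gene is *up* when ``p_adjusted < alpha`` and
    ``log2_fold_change >= lfc_min`` (fold-change boundary inclusive,
    alpha boundary exclusive); *down* mirrors with ``<= -lfc_min``.
    The returned sets share a universe of all tested genes unless
    ``universe_size`` overrides it.
    """
    if lfc_min <= 0 or alpha <= 0:
        raise ValueError("gates must be positive")
    tested = de_results[de_results["tested"].astype(bool)] if "tested" in de_results else de_results
    sig = tested["p_adjusted"] < alpha
    up = set(tested.index[sig & (tested["log2_fold_change"] >= lfc_min)])
    down = set(tested.index[sig & (tested["log2_fold_change"] <= -lfc_min)])
    if universe_size is None:
        universe_size = max(len(tested), 1)
    de_results.loc[list(up), "direction"] = "up"
    de_results.loc[list(down), "direction"] = "down"
    return (
        GeneSet("up", up, universe_size),
        GeneSet("down", down, universe_size),
    )


def overlap_test(
    set_a: GeneSet | set, set_b: GeneSet | set, universe_size: int | None = None
) -> tuple[GeneSet, float]:
    """Upper-tail hypergeometric test for the overlap of two gene sets.

    With a universe of ``N`` genes, ``|A|`` successes and ``|B|`` draws,
    returns ``P(X >= |A & B|)``.  An empty intersection returns p = 1.
    """
    members_a = set_a.members if isinstance(set_a, GeneSet) else set(set_a)
    members_b = set_b.members if isinstance(set_b, GeneSet) else set(set_b)
    if universe_size is None:
        sizes = [s.universe_size for s in (set_a, set_b) if isinstance(s, GeneSet)]
        universe_size = max(sizes) if sizes else RBP_UNIVERSE_SIZE
    if len(members_a) > universe_size or len(members_b) > universe_size:
        raise ValueError("set larger than the stated universe")
    inter = members_a & members_b
    p = hypergeom_upper_tail(len(inter), universe_size, len(members_a), len(members_b))
    return GeneSet("intersection", inter, universe_size), p


def hypergeom_upper_tail(k: int, universe: int, successes: int, draws: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, successes, draws)."""
    if successes > universe or draws > universe:
        raise ValueError("successes and draws cannot exceed the universe")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, successes, draws))


def group_expression_comparison(
    values_a, values_b, exact_max_n: int = 25
) -> tuple[tuple[float, float], float]:
    """Two-sided Wilcoxon rank-sum comparison of two expression groups.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and no ties span the groups, otherwise
    the tie-corrected normal approximation with continuity correction.

    Returns ``((median_a, median_b), p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return (float(np.median(a)), float(np.median(b))), float(res.pvalue)


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the test condition minus the same
    difference in the control condition; the returned fold change is
    ``2 ** -ddCt``.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("cycle-threshold values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
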