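"""PSI quantification and replicate-aware differential splicing.

Splicing events come in five flavours — exon skipping (SE), mutually
exclusive exons (MXE), alternative 5'/3' splice sites (A5SS/A3SS) and
intron retention (RI) — each summarised by junction reads supporting the
inclusion isoform (I) versus the skipping isoform (S).  Percent spliced
in is the effective-length-normalised inclusion fraction

    PSI = (I / lI) / (I / lI + S / lS)

where lI and lS count the junctions informative for each isoform.  The
differential test compares a shared-PSI binomial model against separate
per-condition PSI values with a 1-df likelihood-ratio test on counts
pooled across replicates, followed by Benjamini-Hochberg adjustment
within each event type; a beta-binomial variant absorbing replicate
overdispersion is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize
from scipy.special import expit

from .expression import benjamini_hochberg, hypergeom_upper_tail

__all__ = [
    "SplicingEvent",
    "EVENT_TYPES",
    "DEFAULT_EFFECTIVE_LENGTHS",
    "compute_psi",
    "differential_splicing",
    "apply_splicing_gates",
    "summarize_by_type",
    "gene_set_splicing_enrichment",
]

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

#: Junction-count effective lengths per event type: the inclusion isoform
#: of SE/A5SS/A3SS is supported by two junctions vs one for skipping;
#: both MXE isoforms span two junctions; RI inclusion (retention) is read
#: from the two exon-intron boundaries vs one intron-excising junction.
DEFAULT_EFFECTIVE_LENGTHS = {
    "SE": (2.0, 1.0),
    "MXE": (2.0, 2.0),
    "A5SS": (2.0, 1.0),
    "A3SS": (2.0, 1.0),
    "RI": (2.0, 1.0),
}


@dataclass
class SplicingEvent:
    """A typed splicing event with replicate junction counts.

    ``inclusion_counts`` / ``skipping_counts`` map condition name to an
    integer array with one entry per replicate.  ``start``/``end`` are
    0-based half-open coordinates of the alternative segment (the cassette
    exon for SE, the retained intron for RI, the variable region for the
    other types).
    """

    event_id: str
    event_type: str
    gene_id: str = ""
    chrom: str = ""
    strand: str = "+"
    start: int = 0
    end: int = 0
    inclusion_counts: dict = field(default_factory=dict)
    skipping_counts: dict = field(default_factory=dict)
    effective_length_inclusion: float | None = None
    effective_length_skipping: float | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        li, ls = DEFAULT_EFFECTIVE_LENGTHS[self.event_type]
        if self.effective_length_inclusion is None:
            self.effective_length_inclusion = li
        if self.effective_length_skipping is None:
            self.effective_length_skipping = ls
        if self.effective_length_inclusion <= 0 or self.effective_length_skipping <= 0:
            raise ValueError("effective lengths must be positive")
        for d in (self.inclusion_counts, self.skipping_counts):
            for cond, arr in d.items():
                arr = np.asarray(arr, dtype=int)
                if np.any(arr < 0):
                    raise ValueError("junction counts must be non-negative")
                d[cond] = arr

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_psi(inclusion, skipping, l_inclusion: float = 2.0,
                l_skipping: float = 1.0):
    """Percent spliced in from inclusion/skipping junction counts.

    Vectorised; replicates with zero total counts are unquantifiable and
    return NaN.  With equal effective lengths this reduces to
    ``I / (I + S)``.
    """
    inc = np.asarray(inclusion, dtype=float)
    skp = np.asarray(skipping, dtype=float)
    if l_inclusion <= 0 or l_skipping <= 0:
        raise ValueError("effective lengths must be positive")
    num = inc / l_inclusion
    den = num + skp / l_skipping
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if np.ndim(psi) == 0:
        return float(psi)
    return psi


def _g_statistic(i1: float, s1: float, i2: float, s2: float) -> float:
    """2 x log likelihood ratio for separate vs shared binomial proportions."""
    obs = np.array([[i1, s1], [i2, s2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or np.any(row == 0):
        return 0.0
    exp = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def _betabinom_loglik(i: np.ndarray, n: np.ndarray, p: float, rho: float) -> float:
    if rho <= 1e-9:
        return float(stats.binom.logpmf(i, n, p).sum())
    conc = (1.0 - rho) / rho
    a, b = max(p * conc, 1e-9), max((1.0 - p) * conc, 1e-9)
    return float(stats.betabinom.logpmf(i, n, a, b).sum())


def _betabinom_lrt(i1, n1, i2, n2) -> float:
    """1-df LRT with a common beta-binomial overdispersion rho."""
    i1, n1, i2, n2 = (np.asarray(x, dtype=int) for x in (i1, n1, i2, n2))

    def nll_null(theta):
        p, rho = expit(theta[0]), expit(theta[1])
        return -(_betabinom_loglik(i1, n1, p, rho) + _betabinom_loglik(i2, n2, p, rho))

    def nll_alt(theta):
        p1, p2, rho = expit(theta[0]), expit(theta[1]), expit(theta[2])
        return -(_betabinom_loglik(i1, n1, p1, rho) + _betabinom_loglik(i2, n2, p2, rho))

    p0 = np.clip((i1.sum() + i2.sum()) / max(n1.sum() + n2.sum(), 1), 1e-4, 1 - 1e-4)
    t0 = np.log(p0 / (1 - p0))
    r0 = np.log(0.01 / 0.99)
    res0 = optimize.minimize(nll_null, [t0, r0], method="Nelder-Mead")
    res1 = optimize.minimize(nll_alt, [t0, t0, r0], method="Nelder-Mead")
    return max(0.0, 2.0 * (res0.fun - res1.fun))


def differential_splicing(
    events: list[SplicingEvent],
    condition_labels: tuple[str, str] = ("control", "knockdown"),
    method: str = "pooled",
    fdr_scope: str = "per_type",
) -> pd.DataFrame:
    """Replicate-aware differential-splicing test across two conditions.

    Per event, replicate counts are pooled within condition and a
    shared-proportion binomial model is compared against separate
    per-condition proportions with a 1-df chi-square LRT (a G-test on the
    2x2 inclusion/skipping table).  ``method="betabinom"`` replaces the
    pooled binomial with a beta-binomial likelihood over the replicate
    counts, absorbing between-replicate overdispersion.

    dPSI is mean replicate PSI of ``condition_labels[0]`` minus that of
    ``condition_labels[1]``; with the default orientation (control,
    knockdown), positive dPSI means "more included in control".

    BH adjustment runs within each event type (``fdr_scope="per_type"``)
    or across all tested events (``"global"``).  Events quantifiable in
    only one condition are reported untested with NaN statistics.
    """
    c1, c2 = condition_labels
    rows = []
    for ev in events:
        i1 = np.asarray(ev.inclusion_counts.get(c1, []), dtype=float)
        s1 = np.asarray(ev.skipping_counts.get(c1, []), dtype=float)
        i2 = np.asarray(ev.inclusion_counts.get(c2, []), dtype=float)
        s2 = np.asarray(ev.skipping_counts.get(c2, []), dtype=float)
        li, ls = ev.effective_length_inclusion, ev.effective_length_skipping
        psi1 = compute_psi(i1, s1, li, ls)
        psi2 = compute_psi(i2, s2, li, ls)
        q1 = np.isfinite(psi1).sum() if psi1.size else 0
        q2 = np.isfinite(psi2).sum() if psi2.size else 0
        tested = bool(q1 >= 1 and q2 >= 1)
        if tested:
            mean1 = float(np.nanmean(psi1))
            mean2 = float(np.nanmean(psi2))
            dpsi = mean1 - mean2
            if method == "pooled":
                g = _g_statistic(i1.sum(), s1.sum(), i2.sum(), s2.sum())
            elif method == "betabinom":
                g = _betabinom_lrt(i1, i1 + s1, i2, i2 + s2)
            else:
                raise ValueError(f"unknown method {method!r}")
            p = float(stats.chi2.sf(g, df=1))
        else:
            mean1 = mean2 = dpsi = g = p = np.nan
        rows.append((ev.event_id, ev.event_type, ev.gene_id, mean1, mean2,
                     dpsi, g, p, tested))
    table = pd.DataFrame(
        rows,
        columns=["event_id", "event_type", "gene_id", f"psi_{c1}", f"psi_{c2}",
                 "dpsi", "lrt_stat", "p", "tested"],
    ).set_index("event_id")
    table.attrs["condition_labels"] = (c1, c2)

    table["fdr"] = np.nan
    mask = table["tested"].to_numpy()
    if fdr_scope == "per_type":
        for etype in table.loc[mask, "event_type"].unique():
            sel = mask & (table["event_type"] == etype).to_numpy()
            table.loc[sel, "fdr"] = benjamini_hochberg(table.loc[sel, "p"])
    elif fdr_scope == "global":
        table.loc[mask, "fdr"] = benjamini_hochberg(table.loc[mask, "p"])
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return table


def apply_splicing_gates(
    table: pd.DataFrame, dpsi_min: float = 0.1, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Flag significant events and record the favoured condition.

    Significant iff ``|dPSI| > dpsi_min`` (strict) and ``fdr < fdr_alpha``.
    ``favored`` names the condition with the higher inclusion level for
    significant events, else "none".  Returns a copy with ``significant``
    and ``favored`` columns.
    """
    if not (0 < dpsi_min < 1) or not (0 < fdr_alpha < 1):
        raise ValueError("gates must lie in (0, 1)")
    out = table.copy()
    c1, c2 = table.attrs.get("condition_labels", ("condition1", "condition2"))
    sig = (
        out["tested"].astype(bool)
        & (out["dpsi"].abs() > dpsi_min)
        & (out["fdr"] < fdr_alpha)
    )
    out["significant"] = sig
    out["favored"] = "none"
    out.loc[sig & (out["dpsi"] > 0), "favored"] = c1
    out.loc[sig & (out["dpsi"] < 0), "favored"] = c2
    out.attrs["condition_labels"] = (c1, c2)
    return out


def summarize_by_type(table: pd.DataFrame) -> pd.DataFrame:
    """Per-event-type counts of tested/significant events and genes.

    Requires the gated table (with a ``significant`` column) carrying
    ``gene_id`` per row.
    """
    if "significant" not in table:
        raise ValueError("apply_splicing_gates must run before summarize_by_type")
    rows = []
    for etype in EVENT_TYPES:
        sub = table[table["event_type"] == etype]
        sig = sub[sub["significant"]]
        rows.append((
            etype,
            int(sub["tested"].sum()),
            int(len(sig)),
            int(sig["gene_id"].replace("", np.nan).dropna().nunique()),
        ))
    return pd.DataFrame(
        rows, columns=["event_type", "n_tested", "n_significant", "n_genes"]
    ).set_index("event_type")


def gene_set_splicing_enrichment(affected_genes, query_set, background_genes) -> float:
    """Hypergeometric enrichment of splicing-affected genes in a query set.

    Population = background genes (e.g. all multi-exon genes with junction
    coverage), successes = affected genes within the background, draws =
    the query set; returns the upper-tail p for the observed overlap.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("background gene set is empty")
    query = set(query_set)
    if not query <= background:
        raise ValueError("query set must be contained in the background")
    affected = set(affected_genes) & background
    k = len(affected & query)
    return hypergeom_upper_tail(k, len(background), len(affected), len(query))
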