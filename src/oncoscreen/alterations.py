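"""Genomic-alteration burden and miRNA-target enrichment tests.

Two null models decide whether a candidate gene set is unusual:

* a permutation test drawing random same-size gene sets from the
  universe and comparing the fraction of samples carrying at least one
  alteration (copy-number change, missense or truncating mutation) in
  the set, with the add-one empirical p of Phipson & Smyth; and
* an upper-tail hypergeometric test for the overlap between a miRNA's
  target genes and the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import hypergeom_upper_tail

__all__ = [
    "AlterationMatrix",
    "MirnaTargetMap",
    "altered_sample_fraction",
    "random_set_enrichment",
    "mirna_enrichment",
]


@dataclass
class AlterationMatrix:
    """Binary sample x gene alteration indicator matrix."""

    sample_ids: list[str]
    gene_ids: list[str]
    altered: np.ndarray  # shape (n_samples, n_genes), entries {0, 1}

    def __post_init__(self) -> None:
        self.altered = np.asarray(self.altered)
        if self.altered.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("alteration matrix shape does not match ids")
        if not np.all(np.isin(self.altered, [0, 1])):
            raise ValueError("alteration entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.altered, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class MirnaTargetMap:
    """miRNA -> target gene sets inside a finite gene universe."""

    targets: dict[str, set[str]] = field(default_factory=dict)
    universe_size: int = 0

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            genes = set(genes)
            if len(genes) > self.universe_size:
                raise ValueError(
                    f"{mirna} has {len(genes)} targets, exceeding universe "
                    f"size {self.universe_size}"
                )
            self.targets[mirna] = genes


def altered_sample_fraction(matrix: AlterationMatrix, gene_set) -> float:
    """Fraction of samples with >= 1 altered gene in the set."""
    gene_set = set(gene_set)
    unknown = gene_set - set(matrix.gene_ids)
    if unknown:
        raise KeyError(f"genes absent from the alteration matrix: {sorted(unknown)}")
    if not gene_set:
        return 0.0
    cols = [matrix.gene_ids.index(g) for g in gene_set]
    hit = matrix.altered[:, cols].any(axis=1)
    return float(hit.mean())


def random_set_enrichment(
    matrix: AlterationMatrix,
    target_set,
    universe=None,
    n_iter: int = 100_000,
    seed: int | np.random.Generator = 0,
    statistic: str = "sample_fraction",
) -> dict:
    """Random-gene-set permutation test for alteration burden.

    Draws ``n_iter`` uniform subsets of ``universe`` of the same size as
    ``target_set`` (without replacement within a set, independently
    across iterations) and compares the observed statistic against the
    null draws.  The default statistic is the fraction of samples with
    at least one altered gene in the set; ``statistic="pair_count"``
    instead totals altered gene-sample pairs.

    The empirical p is ``(r + 1) / (n_iter + 1)`` with ``r`` the number
    of null statistics >= observed, so it can never reach zero.

    Returns a dict with ``observed``, ``p``, ``n_iter``, and summary
    statistics of the null distribution.
    """
    target_set = set(target_set)
    if universe is None:
        universe = list(matrix.gene_ids)
    universe = list(universe)
    if len(target_set) > len(universe):
        raise ValueError("target set larger than the universe")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    col_of = {g: j for j, g in enumerate(matrix.gene_ids)}
    missing = [g for g in universe if g not in col_of]
    if missing:
        raise KeyError(f"universe genes absent from the matrix: {missing[:5]}")
    uni_cols = np.asarray([col_of[g] for g in universe])
    mat = matrix.altered.astype(bool)

    def stat_for(cols: np.ndarray) -> float:
        sub = mat[:, cols]
        if statistic == "sample_fraction":
            return float(sub.any(axis=1).mean())
        if statistic == "pair_count":
            return float(sub.sum())
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat_for(np.asarray([col_of[g] for g in target_set]))
    k = len(target_set)
    null = np.empty(n_iter)
    # batched vectorized sampling of index subsets
    batch = max(1, int(2e7 // (mat.shape[0] * max(k, 1))))
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        picks = np.argsort(rng.random((b, uni_cols.size)), axis=1)[:, :k]
        sub = mat[:, uni_cols[picks]]  # (n_samples, b, k)
        if statistic == "sample_fraction":
            null[done:done + b] = sub.any(axis=2).mean(axis=0)
        else:
            null[done:done + b] = sub.sum(axis=(0, 2))
        done += b
    r = int(np.sum(null >= observed))
    return {
        "observed": observed,
        "p": (r + 1) / (n_iter + 1),
        "n_iter": n_iter,
        "set_size": k,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_iter > 1 else 0.0,
        "null_q95": float(np.quantile(null, 0.95)),
        "statistic": statistic,
    }


def mirna_enrichment(target_map: MirnaTargetMap, rbp_set) -> pd.DataFrame:
    """Per-miRNA hypergeometric enrichment of targets in a gene set.

    For each miRNA with target set T inside a universe of N genes, tests
    ``P(X >= |T & rbp_set|)`` for X hypergeometric with ``|T|`` successes
    and ``|rbp_set|`` draws.  Returns a DataFrame indexed by miRNA with
    ``n_targets``, ``overlap``, ``p`` sorted by p.
    """
    rbp_set = set(rbp_set)
    if len(rbp_set) > target_map.universe_size:
        raise ValueError("gene set larger than the target-map universe")
    rows = []
    for mirna, targets in target_map.targets.items():
        k = len(targets & rbp_set)
        p = hypergeom_upper_tail(k, target_map.universe_size, len(targets), len(rbp_set))
        rows.append((mirna, len(targets), k, p))
    df = pd.DataFrame(rows, columns=["mirna", "n_targets", "overlap", "p"])
    return df.set_index("mirna").sort_values("p")
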