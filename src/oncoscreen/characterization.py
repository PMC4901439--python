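"""Sequence-level characterisation of regulated exons and introns.

After the differential-splicing stage, events are classified as
constitutive (control PSI at the boundary: 1 for exons, 0 for retained
introns) or alternative, the affected proportion per class is compared
with a two-proportion chi-square test, and the regulated groups are
contrasted on segment length, GC content and donor/acceptor splice-site
strength with Wilcoxon rank-sum tests.

Splice sites are scored with a position-weight-matrix log-odds model
over the canonical windows: donor = 9-mer (3 exonic + 6 intronic bases),
acceptor = 23-mer (20 intronic + 3 exonic).  The scorer is trainable
from foreground site collections and accepts any drop-in replacement
with the same window conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import group_expression_comparison

__all__ = [
    "DONOR_WINDOW",
    "ACCEPTOR_WINDOW",
    "EventFeatures",
    "SpliceSiteModel",
    "classify_constitutive",
    "affected_proportion_test",
    "sequence_features",
    "extract_splice_site_windows",
    "train_splice_site_model",
    "score_splice_site",
    "compare_regulation_groups",
    "reverse_complement",
]

#: Donor (5'ss) window: 3 exonic + 6 intronic bases.
DONOR_WINDOW = (3, 6)
#: Acceptor (3'ss) window: 20 intronic + 3 exonic bases.
ACCEPTOR_WINDOW = (20, 3)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGULATION_LABELS = ("higher-in-control", "higher-in-knockdown", "unaffected")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class EventFeatures:
    """Per-event sequence features and regulation/class labels."""

    event_id: str
    event_type: str
    feature_length: int
    gc_percent: float
    donor_score: float = np.nan
    acceptor_score: float = np.nan
    constitutive_class: str = "unclassified"  # constitutive | alternative
    regulation: str = "unaffected"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_percent <= 100.0) and np.isfinite(self.gc_percent):
            raise ValueError("gc_percent must lie in [0, 100]")
        if self.feature_length < 1:
            raise ValueError("feature length must be >= 1")


def classify_constitutive(control_psi_values, event_type: str,
                          epsilon: float = 0.005, mode: str = "mean") -> str:
    """Classify an event as constitutive or alternative from control PSI.

    Exon-type events (SE/MXE/A5SS/A3SS) are constitutive when control PSI
    is 1 (within ``epsilon``); retained introns (RI) when control PSI is 0.
    ``mode="mean"`` applies the rule to the mean across quantifiable
    replicates; ``mode="all"`` requires every replicate to satisfy it.
    """
    psi = np.asarray(control_psi_values, dtype=float)
    psi = psi[np.isfinite(psi)]
    if psi.size == 0:
        return "unclassified"
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if event_type == "RI":
        at_boundary = psi <= epsilon if mode == "all" else psi.mean() <= epsilon
    else:
        at_boundary = psi >= 1 - epsilon if mode == "all" else psi.mean() >= 1 - epsilon
    return "constitutive" if np.all(at_boundary) else "alternative"


def affected_proportion_test(classes, affected) -> dict:
    """Two-proportion test of affected rates in constitutive vs alternative.

    ``classes`` holds "constitutive"/"alternative" labels and ``affected``
    the per-event significance flags.  Uses the 2x2 chi-square test with
    continuity correction (the R ``prop.test`` convention).
    """
    classes = np.asarray(list(classes))
    affected = np.asarray(list(affected), dtype=bool)
    table = []
    props = {}
    for cls in ("constitutive", "alternative"):
        mask = classes == cls
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"class {cls!r} has no members")
        k = int(affected[mask].sum())
        table.append([k, n - k])
        props[cls] = k / n
    obs = np.asarray(table)
    if obs[:, 0].sum() == 0 or obs[:, 1].sum() == 0:
        p = 1.0
        chi2 = 0.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=True)
    return {
        "proportion_constitutive": props["constitutive"],
        "proportion_alternative": props["alternative"],
        "chi2": float(chi2),
        "p": float(p),
    }


def _get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) from a dict of strings or a
    pyfaidx.Fasta-like mapping."""
    try:
        ref = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    if start < 0 or end > len(ref):
        raise IndexError(
            f"coordinates {chrom}:{start}-{end} outside sequence of length {len(ref)}"
        )
    return str(ref[start:end]).upper()


def sequence_features(event, genome) -> tuple[int, float]:
    """Length and GC% of an event's alternative segment.

    GC is strand-independent; ambiguous bases (non-ACGT) are excluded
    from the denominator with a warning when present.  ``event`` needs
    ``chrom``, ``start``, ``end`` attributes; ``genome`` maps chromosome
    name to sequence (plain dict of strings or an indexed FASTA).
    """
    seq = _get_sequence(genome, event.chrom, event.start, event.end)
    length = event.end - event.start
    gc = sum(seq.count(b) for b in "GC")
    unambiguous = sum(seq.count(b) for b in _BASES)
    n_ambiguous = len(seq) - unambiguous
    if n_ambiguous:
        warnings.warn(
            f"{event.chrom}:{event.start}-{event.end}: {n_ambiguous} ambiguous "
            "bases excluded from GC denominator"
        )
    if unambiguous == 0:
        return length, float("nan")
    return length, 100.0 * gc / unambiguous


def extract_splice_site_windows(event, genome) -> tuple[str, str]:
    """Donor and acceptor windows flanking an event's alternative segment.

    For an exon segment [start, end) on the + strand the donor window is
    the last 3 exonic bases plus the first 6 intronic bases downstream,
    and the acceptor window the 20 intronic bases upstream plus the first
    3 exonic bases.  For an RI event the segment is the intron, so the
    windows sit just inside/outside its boundaries with the same
    conventions.  Minus-strand events are reverse-complemented.
    """
    d_ex, d_in = DONOR_WINDOW
    a_in, a_ex = ACCEPTOR_WINDOW
    s, e, chrom = event.start, event.end, event.chrom
    fetch = lambda a, b: _get_sequence(genome, chrom, a, b)
    is_intron = event.event_type == "RI"
    if event.strand == "+":
        if is_intron:  # exonic bases lie outside the segment
            donor = fetch(s - d_ex, s + d_in)
            acceptor = fetch(e - a_in, e + a_ex)
        else:  # exonic bases lie inside the segment
            donor = fetch(e - d_ex, e + d_in)
            acceptor = fetch(s - a_in, s + a_ex)
        return donor, acceptor
    # minus strand: transcript runs right-to-left on the genome
    if is_intron:
        donor = reverse_complement(fetch(e - d_in, e + d_ex))
        acceptor = reverse_complement(fetch(s - a_ex, s + a_in))
    else:
        donor = reverse_complement(fetch(s - d_in, s + d_ex))
        acceptor = reverse_complement(fetch(e - a_ex, e + a_in))
    return donor, acceptor


@dataclass
class SpliceSiteModel:
    """Position-weight-matrix log-odds scorer for one site type.

    ``foreground`` is a (window_length, 4) per-position frequency matrix
    (columns A, C, G, T); ``background`` either a matching matrix or a
    length-4 composition broadcast across positions.  Scores are summed
    per-position ``log2(foreground / background)`` in bits.
    """

    site_type: str  # "donor" | "acceptor"
    foreground: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5

    @property
    def window_length(self) -> int:
        return self.foreground.shape[0]

    def __post_init__(self) -> None:
        expected = sum(DONOR_WINDOW) if self.site_type == "donor" else sum(ACCEPTOR_WINDOW)
        self.foreground = np.asarray(self.foreground, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.ndim == 1:
            self.background = np.tile(self.background, (self.foreground.shape[0], 1))
        if self.foreground.shape != (expected, 4):
            raise ValueError(
                f"{self.site_type} foreground must be ({expected}, 4), "
                f"got {self.foreground.shape}"
            )
        if not np.allclose(self.foreground.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("foreground frequencies must sum to 1 per position")
        if np.any(self.foreground <= 0) or np.any(self.background <= 0):
            raise ValueError(
                "zero probabilities in the model; train with a positive pseudocount"
            )

    def to_dict(self) -> dict:
        return {
            "site_type": self.site_type,
            "foreground": self.foreground.tolist(),
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpliceSiteModel":
        return cls(
            site_type=d["site_type"],
            foreground=np.asarray(d["foreground"]),
            background=np.asarray(d["background"]),
            pseudocount=d.get("pseudocount", 0.5),
        )


def train_splice_site_model(
    foreground_sites,
    site_type: str,
    background_sites=None,
    background_composition=None,
    pseudocount: float = 0.5,
) -> SpliceSiteModel:
    """Train a PWM log-odds splice-site scorer.

    ``foreground_sites`` are equal-length windows of the site type's
    canonical width; the background is either another site collection or
    a base composition (default uniform).  A positive pseudocount is
    required so unseen bases stay scorable.
    """
    width = sum(DONOR_WINDOW) if site_type == "donor" else sum(ACCEPTOR_WINDOW)

    def count_matrix(seqs) -> np.ndarray:
        counts = np.full((width, 4), float(pseudocount))
        for i, seq in enumerate(seqs):
            seq = seq.upper()
            if len(seq) != width:
                raise ValueError(
                    f"sequence {i} has length {len(seq)}, expected {width} "
                    f"for a {site_type} window"
                )
            for pos, base in enumerate(seq):
                j = _BASE_INDEX.get(base)
                if j is not None:
                    counts[pos, j] += 1
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(counts <= 0):
            raise ValueError(
                "unobserved base with zero pseudocount; scores would be infinite"
            )
        return counts / totals

    fg = count_matrix(list(foreground_sites))
    if background_sites is not None:
        bg = count_matrix(list(background_sites))
    elif background_composition is not None:
        bg = np.asarray(background_composition, dtype=float)
        bg = bg / bg.sum()
    else:
        bg = np.full(4, 0.25)
    return SpliceSiteModel(site_type=site_type, foreground=fg, background=bg,
                           pseudocount=pseudocount)


def score_splice_site(model: SpliceSiteModel, window: str) -> float:
    """Log-odds score of a window in bits under a PWM model.

    Non-ACGT positions are skipped with a warning (contributing 0).
    """
    window = window.upper()
    if len(window) != model.window_length:
        raise ValueError(
            f"window length {len(window)} does not match the "
            f"{model.site_type} model ({model.window_length})"
        )
    score = 0.0
    skipped = 0
    lod = np.log2(model.foreground / model.background)
    for pos, base in enumerate(window):
        j = _BASE_INDEX.get(base)
        if j is None:
            skipped += 1
            continue
        score += lod[pos, j]
    if skipped:
        warnings.warn(f"{skipped} ambiguous positions skipped in scoring")
    return float(score)


def compare_regulation_groups(
    features: pd.DataFrame,
    group_a: str = "higher-in-knockdown",
    group_b: str = "higher-in-control",
    feature_columns=("feature_length", "gc_percent", "donor_score", "acceptor_score"),
) -> pd.DataFrame:
    """Median comparison of sequence features between regulation groups.

    For each feature column, reports the two group medians and the
    two-sided Wilcoxon rank-sum p (exact for small tie-free groups).
    ``features`` must carry a ``regulation`` column.  Comparisons where a
    group is empty or a feature is all-NaN are skipped with a warning.
    """
    if "regulation" not in features:
        raise ValueError("features must carry a 'regulation' column")
    rows = []
    for col in feature_columns:
        if col not in features:
            continue
        a = features.loc[features["regulation"] == group_a, col].dropna().to_numpy()
        b = features.loc[features["regulation"] == group_b, col].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            warnings.warn(f"skipping {col}: empty regulation group")
            continue
        (med_a, med_b), p = group_expression_comparison(a, b)
        rows.append((col, a.size, b.size, med_a, med_b, p))
    return pd.DataFrame(
        rows,
        columns=["feature", f"n_{group_a}", f"n_{group_b}",
                 f"median_{group_a}", f"median_{group_b}", "p"],
    ).set_index("feature")
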