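"""Ground-truth synthetic data for every stage of the screen.

The generator emulates the shape of the study's inputs — negative-
binomial gene counts with planted differential expression, an
expression-stratified survival cohort with a proportional-hazards
effect, a sparse binary alteration matrix, and junction counts drawn
around true PSI values with planted dPSI — so every downstream stage can
be tested against known truth without any external data.

Each splicing event also receives a simulated sequence context (segment
length, GC content, donor/acceptor windows written into a synthetic
genome) in which regulated events follow planted qualitative trends:
exons excluded upon knockdown are shorter, GC-poorer and carry stronger
splice sites than exons excluded in control, while introns retained upon
knockdown are shorter and GC-richer with no splice-site difference.

One master seed drives everything; each generator derives an independent
substream labelled by stage name, so stages are reproducible in
isolation.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .expression import CountMatrix
from .survival import SurvivalCohort
from .alterations import AlterationMatrix
from .splicing import SplicingEvent, DEFAULT_EFFECTIVE_LENGTHS, EVENT_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "stage_rng",
    "simulate_counts",
    "simulate_survival",
    "simulate_alterations",
    "simulate_splicing_events",
    "DONOR_CONSENSUS",
    "ACCEPTOR_CONSENSUS",
]

#: Canonical donor 9-mer (3 exonic + 6 intronic) used as the "strong"
#: site consensus: MAG | GTRAGT collapsed to a single sequence.
DONOR_CONSENSUS = "CAGGTAAGT"
#: Canonical acceptor 23-mer (20 intronic + 3 exonic): polypyrimidine
#: tract ending in the invariant AG, then the first exonic bases.
ACCEPTOR_CONSENSUS = "T" * 16 + "TCAG" + "GTT"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-scale conditions for the synthetic data generator.

    Defaults echo the screen's scale: a 1542-gene RNA-binding-protein
    universe, triplicate knockdown arms, a planted dPSI above the 0.1
    reporting gate, and RNA-seq-typical depth and dispersion.
    """

    seed: int = 0
    n_genes: int = 1542
    n_rbp_genes: int = 1542
    samples_per_group: int = 10
    de_fraction: float = 0.2
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.05
    depth_mean: float = 5e5
    survival_hazard_ratio: float = 3.0
    censoring_fraction: float = 0.2
    alteration_rate_background: float = 0.01
    n_events_per_type: int = 600
    event_depth: float = 200.0
    planted_dpsi: float = 0.3
    replicates: int = 3

    # generator conditions beyond the flat screen parameters -----------
    baseline_log_sd: float = 1.0          # spread of per-gene baseline (natural log)
    depth_log_sd: float = 0.15            # library-size variability
    survival_median_days: float = 400.0   # baseline-arm exponential median
    survival_cohort_size: int = 300       # registry cohorts dwarf the RNA-seq groups
    survival_high_fraction: float = 0.25  # cohort fraction in the high-expression arm
    alternative_fraction: float = 0.5     # events with interior control PSI
    regulated_fraction_alternative: float = 0.25
    regulated_fraction_constitutive: float = 0.06
    knockdown_direction_fraction: float = 0.7  # regulated alt. exons excluded upon KD
    exon_length_medians: dict = field(
        default_factory=lambda: {"higher-in-control": 100.0,
                                 "higher-in-knockdown": 300.0,
                                 "unaffected": 160.0})
    intron_length_medians: dict = field(
        default_factory=lambda: {"higher-in-knockdown": 400.0,
                                 "higher-in-control": 1400.0,
                                 "unaffected": 800.0})
    length_log_sd: float = 0.45
    exon_gc_means: dict = field(
        default_factory=lambda: {"higher-in-control": 42.0,
                                 "higher-in-knockdown": 54.0,
                                 "unaffected": 48.0})
    intron_gc_means: dict = field(
        default_factory=lambda: {"higher-in-knockdown": 58.0,
                                 "higher-in-control": 44.0,
                                 "unaffected": 50.0})
    gc_sd: float = 5.0
    splice_site_consensus_bias: dict = field(
        default_factory=lambda: {"higher-in-control": 0.85,
                                 "higher-in-knockdown": 0.0,
                                 "unaffected": 0.5})
    flank_length: int = 60
    events_per_gene: int = 3

    def validate(self) -> None:
        for name in ("de_fraction", "censoring_fraction",
                     "alteration_rate_background", "alternative_fraction",
                     "regulated_fraction_alternative",
                     "regulated_fraction_constitutive",
                     "knockdown_direction_fraction", "survival_high_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.censoring_fraction >= 1.0:
            raise ValueError("censoring_fraction must be < 1")
        for name in ("n_genes", "n_rbp_genes", "samples_per_group",
                     "n_events_per_type", "replicates", "survival_cohort_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("nb_dispersion", "survival_hazard_ratio", "depth_mean",
                     "event_depth"):
            if getattr(self, name) <= 0 and not (name == "nb_dispersion"
                                                 and getattr(self, name) == 0):
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.planted_dpsi < 1.0):
            raise ValueError("planted_dpsi must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth recorded alongside each simulated dataset."""

    de_up: set = field(default_factory=set)
    de_down: set = field(default_factory=set)
    survival_genes: set = field(default_factory=set)
    survival_high_samples: set = field(default_factory=set)
    true_psi: dict = field(default_factory=dict)       # event -> {condition: psi}
    regulation: dict = field(default_factory=dict)     # event -> label
    enriched_alteration_set: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "de_up": sorted(self.de_up),
            "de_down": sorted(self.de_down),
            "survival_genes": sorted(self.survival_genes),
            "survival_high_samples": sorted(self.survival_high_samples),
            "true_psi": self.true_psi,
            "regulation": self.regulation,
            "enriched_alteration_set": sorted(self.enriched_alteration_set),
        }


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named stage under one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, Var mu + alpha mu^2) counts; Poisson when alpha = 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimulationConfig,
    de_up: set | None = None,
    de_down: set | None = None,
    group_labels: tuple[str, str] = ("normal", "tumor"),
    stage: str = "counts",
) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial count matrix with planted fold changes.

    Per-gene baselines are lognormal proportions of a lognormal
    per-sample depth; the designated DE genes receive a multiplicative
    ``2**lfc_effect`` (up) or ``2**-lfc_effect`` (down) shift in the
    second group.  When ``de_up``/``de_down`` are not given they are
    drawn at ``de_fraction`` of the genes, split evenly by direction.
    """
    config.validate()
    rng = stage_rng(config.seed, stage)
    genes = [f"RBP{i:04d}" for i in range(1, config.n_genes + 1)]
    if de_up is None and de_down is None:
        n_de = int(round(config.de_fraction * config.n_genes))
        chosen = rng.choice(config.n_genes, size=n_de, replace=False)
        de_up = {genes[i] for i in chosen[: n_de // 2]}
        de_down = {genes[i] for i in chosen[n_de // 2:]}
    de_up = set(de_up or ())
    de_down = set(de_down or ())
    unknown = (de_up | de_down) - set(genes)
    if unknown:
        raise ValueError(f"planted DE genes outside the universe: {sorted(unknown)[:5]}")

    n = config.samples_per_group
    sample_ids = [f"{group_labels[0]}_{j+1}" for j in range(n)] + [
        f"{group_labels[1]}_{j+1}" for j in range(n)
    ]
    labels = [group_labels[0]] * n + [group_labels[1]] * n

    base = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=config.n_genes)
    props = base / base.sum()
    depth = config.depth_mean * rng.lognormal(0.0, config.depth_log_sd, size=2 * n)

    fold = np.ones(config.n_genes)
    up_idx = [genes.index(g) for g in de_up]
    down_idx = [genes.index(g) for g in de_down]
    fold[up_idx] = 2.0 ** config.lfc_effect
    fold[down_idx] = 2.0 ** -config.lfc_effect

    mu = props[:, None] * depth[None, :]
    mu[:, n:] *= fold[:, None]
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    truth = GroundTruth(de_up=de_up, de_down=de_down)
    return CountMatrix(genes, sample_ids, counts, labels), truth


def _censoring_horizon(hazard: float, fraction: float) -> float:
    """Administrative-censoring horizon tau with C ~ U(0, tau) giving the
    requested expected censored fraction under an Exp(hazard) event time."""
    if fraction <= 0:
        return math.inf
    # P(C < T) = (1 - exp(-hazard*tau)) / (hazard*tau), decreasing in tau
    g = lambda x: (1.0 - math.exp(-x)) / x - fraction
    x = optimize.brentq(g, 1e-9, 1e6)
    return x / hazard


def simulate_survival(
    config: SimulationConfig,
    gene_ids,
    planted_genes: set | None = None,
    stage: str = "survival",
) -> tuple[SurvivalCohort, GroundTruth]:
    """Proportional-hazards exponential cohort with expression strata.

    A fixed fraction of samples forms the high-expression arm; for
    planted genes those samples express at ``2**lfc_effect`` times
    baseline and carry ``survival_hazard_ratio`` times the baseline
    hazard.  Null genes get expression independent of survival.
    Censoring is administrative-uniform at the configured expected
    fraction.
    """
    config.validate()
    if config.survival_hazard_ratio <= 0:
        raise ValueError("hazard ratio must be > 0")
    rng = stage_rng(config.seed, stage)
    gene_ids = list(gene_ids)
    if planted_genes is None:
        planted_genes = set(gene_ids[: max(1, len(gene_ids) // 10)])
    planted_genes = set(planted_genes)
    unknown = planted_genes - set(gene_ids)
    if unknown:
        raise ValueError(f"planted survival genes not in gene_ids: {sorted(unknown)[:5]}")

    n_total = config.survival_cohort_size
    n_high = max(1, int(round(config.survival_high_fraction * n_total)))
    sample_ids = [f"S{j+1:04d}" for j in range(n_total)]
    high = np.zeros(n_total, dtype=bool)
    high[rng.choice(n_total, size=n_high, replace=False)] = True

    lam0 = math.log(2.0) / config.survival_median_days
    hazard = np.where(high, lam0 * config.survival_hazard_ratio, lam0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_fraction > 0:
        tau = _censoring_horizon(lam0, config.censoring_fraction)
        c = rng.uniform(0.0, tau, size=n_total)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n_total, dtype=int)

    baseline = 100.0
    expr = pd.DataFrame(index=pd.Index(sample_ids), columns=gene_ids, dtype=float)
    for g in gene_ids:
        if g in planted_genes:
            # jitter kept well under the stratification margin so the
            # planted arm is exactly the high-expression group
            vals = np.where(
                high,
                baseline * 2.0 ** config.lfc_effect,
                baseline,
            ) * rng.lognormal(0.0, 0.02, size=n_total)
        else:
            vals = baseline * 2.0 ** rng.normal(0.0, 1.5, size=n_total)
        expr[g] = vals

    cohort = SurvivalCohort(sample_ids, time, event, expr)
    truth = GroundTruth(
        survival_genes=planted_genes,
        survival_high_samples={s for s, h in zip(sample_ids, high) if h},
    )
    return cohort, truth


def simulate_alterations(
    config: SimulationConfig,
    universe,
    target_set=None,
    enriched_rate: float | None = None,
    n_samples: int = 273,
    stage: str = "alterations",
) -> AlterationMatrix:
    """Sparse binary sample x gene alteration matrix.

    Background genes are altered independently at
    ``alteration_rate_background`` per sample; ``target_set`` genes, when
    given with ``enriched_rate``, at the elevated rate.
    """
    config.validate()
    universe = list(universe)
    target_set = set(target_set or ())
    if not target_set <= set(universe):
        raise ValueError("target_set must be contained in the universe")
    rate_bg = config.alteration_rate_background
    if enriched_rate is not None and not (0.0 <= enriched_rate <= 1.0):
        raise ValueError("enriched_rate must lie in [0, 1]")
    rng = stage_rng(config.seed, stage)
    rates = np.full(len(universe), rate_bg)
    if enriched_rate is not None:
        for j, g in enumerate(universe):
            if g in target_set:
                rates[j] = enriched_rate
    altered = (rng.random((n_samples, len(universe))) < rates[None, :]).astype(int)
    samples = [f"P{j+1:04d}" for j in range(n_samples)]
    return AlterationMatrix(samples, universe, altered)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """i.i.d. bases with the requested GC fraction (as array of chars)."""
    pg = gc / 2.0
    pa = (1.0 - gc) / 2.0
    return rng.choice(_BASES, size=length, p=[pa, pg, pg, pa])


def _site_kmer(rng: np.random.Generator, consensus: str, bias: float) -> np.ndarray:
    """Per-position: consensus base with probability ``bias``, else uniform."""
    out = rng.choice(_BASES, size=len(consensus))
    use_consensus = rng.random(len(consensus)) < bias
    cons = np.array(list(consensus))
    out[use_consensus] = cons[use_consensus]
    return out


def simulate_splicing_events(
    config: SimulationConfig,
    conditions: tuple[str, str] = ("control", "knockdown"),
) -> tuple[list[SplicingEvent], GroundTruth, dict]:
    """Splicing events with replicate junction counts and sequence context.

    For each of the five event types, control PSI is drawn from a mixture
    of a boundary point mass (1 for exon types, 0 for retained introns —
    the constitutive class) and an interior uniform component.  Regulated
    events (chosen at a higher rate among alternative than constitutive
    events) receive ``planted_dpsi`` in a direction dominated by the
    knockdown: exons lose inclusion, introns gain retention.  Knockdown
    PSI values leaving [0, 1] are clipped with a logged warning.

    Junction counts per replicate are binomial around the effective-
    length-weighted inclusion probability at Poisson(``event_depth``)
    total reads.  A synthetic genome (one chromosome per event type)
    carries each event's segment with planted length, GC and splice-site
    trends, plus flanking sequence.

    Returns ``(events, truth, genome)`` where genome maps chromosome
    name to sequence string.
    """
    config.validate()
    rng = stage_rng(config.seed, "splicing")
    c_ctrl, c_kd = conditions
    events: list[SplicingEvent] = []
    truth = GroundTruth()
    genome: dict[str, str] = {}
    n_clipped = 0

    for etype in EVENT_TYPES:
        li, ls = DEFAULT_EFFECTIVE_LENGTHS[etype]
        chrom = f"chr{etype}"
        chunks: list[np.ndarray] = []
        pos = 0
        is_intron = etype == "RI"
        for k in range(config.n_events_per_type):
            ev_id = f"{etype}_{k+1:05d}"
            gene_id = f"G_{etype}_{k // config.events_per_gene + 1:04d}"

            alternative = rng.random() < config.alternative_fraction
            if alternative:
                psi_ctrl = float(rng.uniform(0.05, 0.75) if is_intron
                                 else rng.uniform(0.25, 0.95))
            else:
                psi_ctrl = 0.0 if is_intron else 1.0

            reg_rate = (config.regulated_fraction_alternative if alternative
                        else config.regulated_fraction_constitutive)
            regulated = rng.random() < reg_rate
            if regulated and config.planted_dpsi > 0:
                if alternative:
                    kd_direction = rng.random() < config.knockdown_direction_fraction
                else:
                    kd_direction = True  # only feasible move off the boundary
                if is_intron:
                    # knockdown favours retention (higher inclusion in KD)
                    delta = config.planted_dpsi if kd_direction else -config.planted_dpsi
                else:
                    # knockdown favours exclusion (higher inclusion in control)
                    delta = -config.planted_dpsi if kd_direction else config.planted_dpsi
                psi_kd = psi_ctrl + delta
                if psi_kd < 0.0 or psi_kd > 1.0:
                    n_clipped += 1
                    psi_kd = min(max(psi_kd, 0.0), 1.0)
                if is_intron:
                    label = "higher-in-knockdown" if kd_direction else "higher-in-control"
                else:
                    label = "higher-in-control" if kd_direction else "higher-in-knockdown"
            else:
                psi_kd = psi_ctrl
                label = "unaffected"

            inc, skp = {}, {}
            for cond, psi in ((c_ctrl, psi_ctrl), (c_kd, psi_kd)):
                totals = rng.poisson(config.event_depth, size=config.replicates)
                p_inc = psi * li / (psi * li + (1.0 - psi) * ls) if psi > 0 else 0.0
                i_counts = rng.binomial(totals, p_inc)
                inc[cond] = i_counts
                skp[cond] = totals - i_counts

            # sequence context ---------------------------------------
            medians = (config.intron_length_medians if is_intron
                       else config.exon_length_medians)
            gcs = (config.intron_gc_means if is_intron else config.exon_gc_means)
            length = max(40, int(round(rng.lognormal(
                math.log(medians[label]), config.length_log_sd))))
            gc_target = float(np.clip(rng.normal(gcs[label], config.gc_sd), 20.0, 80.0))
            if is_intron:
                bias = config.splice_site_consensus_bias["unaffected"]
            else:
                bias = config.splice_site_consensus_bias[label]

            left = _random_sequence(rng, config.flank_length, 0.45)
            seg = _random_sequence(rng, length, gc_target / 100.0)
            right = _random_sequence(rng, config.flank_length, 0.45)
            donor = _site_kmer(rng, DONOR_CONSENSUS, bias)
            acceptor = _site_kmer(rng, ACCEPTOR_CONSENSUS, bias)
            if is_intron:
                # donor: 3 exonic (left flank) + 6 intronic (segment head)
                left[-3:] = donor[:3]
                seg[:6] = donor[3:]
                # acceptor: 20 intronic (segment tail) + 3 exonic (right flank)
                seg[-20:] = acceptor[:20]
                right[:3] = acceptor[20:]
            else:
                # acceptor: 20 intronic (left flank) + 3 exonic (segment head)
                left[-20:] = acceptor[:20]
                seg[:3] = acceptor[20:]
                # donor: 3 exonic (segment tail) + 6 intronic (right flank)
                seg[-3:] = donor[:3]
                right[:6] = donor[3:]

            start = pos + config.flank_length
            end = start + length
            pos = end + config.flank_length
            chunks.extend([left, seg, right])

            events.append(SplicingEvent(
                event_id=ev_id, event_type=etype, gene_id=gene_id,
                chrom=chrom, strand="+", start=start, end=end,
                inclusion_counts=inc, skipping_counts=skp,
                effective_length_inclusion=li, effective_length_skipping=ls,
            ))
            truth.true_psi[ev_id] = {c_ctrl: psi_ctrl, c_kd: psi_kd}
            truth.regulation[ev_id] = label
        genome[chrom] = "".join("".join(c) for c in chunks)

    if n_clipped:
        logger.warning("planted dPSI clipped to [0, 1] for %d events", n_clipped)
    return events, truth, genome
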