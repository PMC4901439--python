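"""End-to-end candidate funnel: DE in two contexts -> overlap -> survival
filter -> alteration/miRNA enrichment -> differential splicing ->
exon/intron characterisation.

``run_screen`` executes the stages in funnel order on simulated inputs
with one configuration and one master seed, writes per-stage tables when
an output directory is given, and returns a JSON-serialisable report
whose candidate counts are non-increasing along the funnel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from ._version import __version__
from .alterations import MirnaTargetMap, altered_sample_fraction, \
    random_set_enrichment, mirna_enrichment
from .characterization import (classify_constitutive, affected_proportion_test,
                               sequence_features, extract_splice_site_windows,
                               train_splice_site_model, score_splice_site,
                               compare_regulation_groups)
from .expression import differential_expression, apply_de_gates, overlap_test
from .simulate import SimulationConfig, simulate_counts, simulate_survival, \
    simulate_alterations, simulate_splicing_events, stage_rng
from .splicing import differential_splicing, apply_splicing_gates, \
    summarize_by_type, gene_set_splicing_enrichment
from .survival import survival_screen

logger = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "run_screen", "load_screen_config"]


@dataclass
class ScreenConfig:
    """One configuration for the whole screen.

    Gate defaults follow the study's reported thresholds: |log2FC| >= 1
    with BH-adjusted p < 0.05 for expression, log-rank p < 0.05 for
    survival, |dPSI| > 0.1 with FDR < 0.05 for splicing, and 100,000
    random sets for the alteration-burden null.
    """

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    lfc_min: float = 1.0
    alpha: float = 0.05
    survival_alpha: float = 0.05
    dpsi_min: float = 0.1
    fdr_alpha: float = 0.05
    n_iter: int = 100_000
    context_overlap: float = 0.5   # planted up-genes shared by both contexts
    survival_planted_fraction: float = 0.5
    run_alterations: bool = True
    run_splicing: bool = True
    run_characterization: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed
        for name in ("alpha", "survival_alpha", "dpsi_min", "fdr_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.lfc_min <= 0:
            raise ValueError("lfc_min must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_screen_config(path, overrides: dict | None = None) -> ScreenConfig:
    """Load a flat YAML key-value config; keys matching SimulationConfig
    fields are routed into the nested simulation block."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if overrides:
        data.update(overrides)
    sim_fields = set(SimulationConfig.__dataclass_fields__)
    screen_fields = set(ScreenConfig.__dataclass_fields__)
    sim_kwargs = dict(data.pop("simulation", {}) or {})
    screen_kwargs = {}
    for k, v in data.items():
        if k in screen_fields:
            screen_kwargs[k] = v
        elif k in sim_fields:
            sim_kwargs[k] = v
        else:
            raise KeyError(f"unknown configuration key {k!r}")
    screen_kwargs["simulation"] = sim_kwargs
    return ScreenConfig(**screen_kwargs)


def _planted_context_sets(config: ScreenConfig) -> tuple[set, set, set, set]:
    """Up/down truth sets for the two contexts with a planted shared core."""
    sim = config.simulation
    rng = stage_rng(config.seed, "context_design")
    genes = [f"RBP{i:04d}" for i in range(1, sim.n_genes + 1)]
    n_de = int(round(sim.de_fraction * sim.n_genes))
    if n_de == 0:
        return set(), set(), set(), set()
    n_up = n_de // 2
    n_core = max(1, int(round(config.context_overlap * n_up)))
    picks = rng.choice(sim.n_genes, size=min(2 * n_de, sim.n_genes), replace=False)
    it = iter(picks.tolist())
    core = {genes[next(it)] for _ in range(n_core)}
    extra_a = {genes[next(it)] for _ in range(n_up - n_core)}
    extra_b = {genes[next(it)] for _ in range(n_up - n_core)}
    down_a = {genes[next(it)] for _ in range(n_de - n_up)}
    down_b = {genes[next(it)] for _ in range(n_de - n_up)}
    return core | extra_a, down_a, core | extra_b, down_b


def run_screen(config: ScreenConfig) -> dict:
    """Run the full simulated screen and return the report dict.

    Stages execute in funnel order; a stage failure marks the report and
    skips dependent stages.  Rerunning with the same seed and config
    reproduces the report (timestamps excluded — none are recorded).
    """
    sim = config.simulation
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": {"name": "oncoscreen", "version": __version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "funnel": {},
    }

    def fail(stage: str, exc: Exception) -> None:
        logger.error("stage %s failed: %s", stage, exc)
        report["stages"][stage] = {"status": "failed", "error": str(exc)}

    # ---- stage 1: differential expression in two contexts ------------
    up_a_truth, down_a_truth, up_b_truth, down_b_truth = _planted_context_sets(config)
    candidates: set = set()
    try:
        ctx = {}
        for name, up_t, down_t, labels in (
            ("gbm", up_a_truth, down_a_truth, ("normal", "tumor")),
            ("gsc", up_b_truth, down_b_truth, ("progenitor", "gsc")),
        ):
            counts, _ = simulate_counts(sim, de_up=up_t, de_down=down_t,
                                        group_labels=labels, stage=f"counts_{name}")
            de = differential_expression(counts, contrast=labels)
            up, down = apply_de_gates(de, config.lfc_min, config.alpha,
                                      universe_size=sim.n_rbp_genes)
            ctx[name] = {"de": de, "up": up, "down": down}
            report["stages"][f"de_{name}"] = {
                "status": "ok",
                "n_tested": int(de["tested"].sum()),
                "n_up": len(up), "n_down": len(down),
                "gates": {"lfc_min": config.lfc_min, "alpha": config.alpha},
            }
            if out_dir:
                ctx[name]["de"].to_csv(out_dir / f"de_{name}.tsv", sep="\t")
        inter, overlap_p = overlap_test(ctx["gbm"]["up"], ctx["gsc"]["up"],
                                        universe_size=sim.n_rbp_genes)
        candidates = set(inter.members)
        report["stages"]["overlap"] = {
            "status": "ok",
            "n_intersection": len(inter),
            "universe": sim.n_rbp_genes,
            "p_hypergeometric": overlap_p,
        }
        report["funnel"] = {
            "up_context_gbm": len(ctx["gbm"]["up"]),
            "up_context_gsc": len(ctx["gsc"]["up"]),
            "intersection": len(inter),
        }
    except Exception as exc:  # pragma: no cover - defensive
        fail("differential_expression", exc)
        return _finish(report, out_dir, exit_ok=False)

    # ---- stage 2: survival filter ------------------------------------
    try:
        planted_surv = set(
            sorted(candidates)[: max(1, int(round(
                config.survival_planted_fraction * len(candidates))))]
        ) if candidates else set()
        cohort, surv_truth = simulate_survival(sim, sorted(candidates) or ["RBP0001"],
                                               planted_genes=planted_surv)
        screen_tbl = survival_screen(cohort, sorted(candidates) or [],
                                     lfc_threshold=config.lfc_min,
                                     alpha=config.survival_alpha)
        selected = set(screen_tbl.index[screen_tbl["selected"]])
        report["stages"]["survival"] = {
            "status": "ok",
            "n_candidates": len(candidates),
            "n_selected": len(selected),
            "gates": {"lfc_threshold": config.lfc_min,
                      "alpha": config.survival_alpha},
        }
        report["funnel"]["survival_selected"] = len(selected)
        if out_dir:
            screen_tbl.to_csv(out_dir / "survival_screen.tsv", sep="\t")
    except Exception as exc:
        fail("survival", exc)
        selected = set()
        report["funnel"]["survival_selected"] = 0

    final_candidates = selected & candidates
    report["funnel"]["final_candidates"] = len(final_candidates)

    # ---- stage 3: alterations and miRNA targeting --------------------
    if config.run_alterations and final_candidates:
        try:
            universe = [f"RBP{i:04d}" for i in range(1, sim.n_rbp_genes + 1)]
            alt = simulate_alterations(sim, universe)
            enr = random_set_enrichment(alt, final_candidates, universe,
                                        n_iter=config.n_iter,
                                        seed=stage_rng(config.seed, "alt_perm"))
            mirna_map = _simulated_mirna_map(config, universe, final_candidates)
            mir = mirna_enrichment(mirna_map, final_candidates)
            report["stages"]["alterations"] = {
                "status": "ok",
                "altered_sample_fraction": enr["observed"],
                "permutation_p": enr["p"],
                "n_iter": enr["n_iter"],
                "top_mirna": mir.index[0] if len(mir) else None,
                "top_mirna_p": float(mir["p"].iloc[0]) if len(mir) else None,
            }
            if out_dir:
                mir.to_csv(out_dir / "mirna_enrichment.tsv", sep="\t")
        except Exception as exc:
            fail("alterations", exc)
    elif config.run_alterations:
        report["stages"]["alterations"] = {"status": "skipped",
                                           "reason": "no final candidates"}

    # ---- stage 4: differential splicing ------------------------------
    gated = None
    events = truth = genome = None
    if config.run_splicing:
        try:
            events, truth, genome = simulate_splicing_events(sim)
            calls = differential_splicing(events)
            gated = apply_splicing_gates(calls, config.dpsi_min, config.fdr_alpha)
            summary = summarize_by_type(gated)
            affected = set(gated.loc[gated["significant"], "gene_id"])
            background = sorted({ev.gene_id for ev in events})
            rng = stage_rng(config.seed, "splice_query")
            query = set(np.random.default_rng(rng.integers(2**31)).choice(
                background, size=min(30, len(background)), replace=False))
            enrich_p = gene_set_splicing_enrichment(affected, query, background)
            report["stages"]["splicing"] = {
                "status": "ok",
                "gates": {"dpsi_min": config.dpsi_min, "fdr_alpha": config.fdr_alpha},
                "n_events_tested": int(gated["tested"].sum()),
                "n_events_significant": int(gated["significant"].sum()),
                "n_genes_affected": len(affected - {""}),
                "per_type": summary.to_dict(orient="index"),
                "random_query_enrichment_p": enrich_p,
            }
            if out_dir:
                gated.to_csv(out_dir / "splicing_calls.tsv", sep="\t")
        except Exception as exc:
            fail("splicing", exc)
            gated = None

    # ---- stage 5: exon/intron characterisation -----------------------
    if config.run_characterization and gated is not None:
        try:
            report["stages"]["characterization"] = characterize_events(
                events, gated, genome)
        except Exception as exc:
            fail("characterization", exc)
    elif config.run_characterization:
        report["stages"]["characterization"] = {
            "status": "skipped", "reason": "splicing stage unavailable"}

    return _finish(report, out_dir, exit_ok=all(
        s.get("status") != "failed" for s in report["stages"].values()))


def _simulated_mirna_map(config: ScreenConfig, universe, candidates) -> MirnaTargetMap:
    """Small synthetic miRNA->target map with one candidate-enriched miRNA."""
    rng = stage_rng(config.seed, "mirna_map")
    targets: dict[str, set] = {}
    uni = list(universe)
    for i in range(17):
        size = int(rng.integers(20, 120))
        targets[f"miR-null-{i+1}"] = set(rng.choice(uni, size=size, replace=False))
    cand = sorted(candidates)
    n_hit = max(1, len(cand) // 3)
    enriched = set(rng.choice(cand, size=n_hit, replace=False))
    enriched |= set(rng.choice(uni, size=40, replace=False))
    targets["miR-124-like"] = enriched
    return MirnaTargetMap(targets, universe_size=len(uni))


def characterize_events(events, gated, genome) -> dict:
    """Classify events, test affected proportions per class, and compare
    regulated groups on length/GC/splice-site strength (SE and RI)."""
    ev_by_id = {ev.event_id: ev for ev in events}
    feats = []
    for ev_id, row in gated.iterrows():
        ev = ev_by_id[ev_id]
        if ev.event_type not in ("SE", "RI"):
            continue
        psi_ctrl = row.get("psi_control", np.nan)
        cls = classify_constitutive([psi_ctrl], ev.event_type)
        length, gc = sequence_features(ev, genome)
        if row["significant"]:
            reg = ("higher-in-control" if row["dpsi"] > 0 else "higher-in-knockdown")
        else:
            reg = "unaffected"
        donor_win, acc_win = extract_splice_site_windows(ev, genome)
        feats.append({
            "event_id": ev_id, "event_type": ev.event_type,
            "constitutive_class": cls, "regulation": reg,
            "feature_length": length, "gc_percent": gc,
            "donor_window": donor_win, "acceptor_window": acc_win,
        })
    feats = pd.DataFrame(feats).set_index("event_id")

    out: dict = {"status": "ok"}
    for etype in ("SE", "RI"):
        sub = feats[feats["event_type"] == etype].copy()
        classified = sub[sub["constitutive_class"] != "unclassified"]
        prop = affected_proportion_test(
            classified["constitutive_class"],
            classified["regulation"] != "unaffected",
        )
        # train the site models on this type's constitutive events
        train = sub[sub["constitutive_class"] == "constitutive"]
        donor_model = train_splice_site_model(train["donor_window"], "donor")
        acceptor_model = train_splice_site_model(train["acceptor_window"], "acceptor")
        sub["donor_score"] = [score_splice_site(donor_model, w)
                              for w in sub["donor_window"]]
        sub["acceptor_score"] = [score_splice_site(acceptor_model, w)
                                 for w in sub["acceptor_window"]]
        comparison = compare_regulation_groups(sub)
        out[etype] = {
            "affected_proportions": prop,
            "group_comparison": comparison.reset_index().to_dict(orient="records"),
        }
    return out


def _finish(report: dict, out_dir: Path | None, exit_ok: bool) -> dict:
    report["ok"] = bool(exit_ok)
    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default), encoding="utf-8")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
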