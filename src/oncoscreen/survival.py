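"""Expression-stratified survival screen.

Candidate genes surviving the two-context expression screen are filtered
by prognosis: for each gene, samples whose expression is at least
``2**lfc_threshold`` times a baseline form the high-expression group, the
two groups' Kaplan-Meier curves are compared with a log-rank test, and
the gene passes when the high group has *worse* survival at the chosen
alpha.  Estimation and testing delegate to lifelines; this module owns
the stratification rule, the direction enforcement, and the screen loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalCohort",
    "SurvivalCurve",
    "stratify_by_expression",
    "kaplan_meier",
    "logrank_test",
    "survival_screen",
]


@dataclass
class SurvivalCohort:
    """Per-sample follow-up time, event indicator and expression values.

    ``expression`` is a (sample x gene) DataFrame aligned to ``sample_ids``.
    ``reference_samples``, when given, define the baseline expression used
    by the fold-change stratification; otherwise the cohort mean is used.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame
    reference_samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ValueError("survival times must be non-negative")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicators must be 0 (censored) or 1 (death)")
        if len(self.sample_ids) != self.time.size or self.time.size != self.event.size:
            raise ValueError("sample_ids, time and event must be aligned")
        if not self.expression.index.equals(pd.Index(self.sample_ids)):
            self.expression = self.expression.reindex(self.sample_ids)
            if self.expression.isna().any().any():
                raise ValueError("expression matrix is not aligned to sample_ids")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def stratify_by_expression(
    cohort: SurvivalCohort, gene: str, lfc_threshold: float = 1.0
) -> np.ndarray:
    """Label samples whose expression is >= 2**threshold times baseline.

    Baseline is the mean expression over ``reference_samples`` when the
    cohort defines them, else the cohort-wide mean.  The boundary is
    inclusive: a sample at exactly the fold-change threshold is high.

    Returns a boolean array aligned to ``cohort.sample_ids``.
    """
    if gene not in cohort.expression.columns:
        raise KeyError(f"gene {gene!r} not in cohort expression")
    expr = cohort.expression[gene].to_numpy(dtype=float)
    if cohort.reference_samples:
        baseline = float(cohort.expression.loc[cohort.reference_samples, gene].mean())
    else:
        baseline = float(expr.mean())
    if baseline <= 0:
        raise ValueError(f"baseline expression for {gene!r} is {baseline}; must be > 0")
    with np.errstate(divide="ignore"):
        lfc = np.log2(np.maximum(expr, 0.0) / baseline)
    return lfc >= lfc_threshold


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    At tied times events are processed before censorings, the standard
    convention.  With no events the curve is flat at 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one sample required")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev_times = table.index.to_numpy(dtype=float)[mask.to_numpy()]
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    return SurvivalCurve(
        times=ev_times,
        survival=surv,
        at_risk=table.loc[mask, "at_risk"].to_numpy(dtype=int),
        events=table.loc[mask, "observed"].to_numpy(dtype=int),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Haenszel) test.

    Returns the 1-df chi-square statistic and its p-value.  If neither
    group has any event the test is undefined and (0, 1) is returned
    with a warning.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank test undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def _observed_minus_expected(times_h, events_h, times_l, events_l) -> float:
    """O - E events in the high group over the shared risk sets.

    Positive values mean the high group dies faster than expected under
    the null, i.e. worse survival.
    """
    all_times = np.concatenate([times_h, times_l])
    all_events = np.concatenate([events_h, events_l])
    in_high = np.concatenate(
        [np.ones_like(times_h, dtype=bool), np.zeros_like(times_l, dtype=bool)]
    )
    o_minus_e = 0.0
    for t in np.unique(all_times[all_events == 1]):
        at_risk = all_times >= t
        n = at_risk.sum()
        n_h = (at_risk & in_high).sum()
        d = ((all_times == t) & (all_events == 1)).sum()
        d_h = ((all_times == t) & (all_events == 1) & in_high).sum()
        o_minus_e += d_h - d * n_h / n
    return float(o_minus_e)


def survival_screen(
    cohort: SurvivalCohort,
    candidate_genes,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    enforce_direction: bool = True,
) -> pd.DataFrame:
    """Per-gene expression-stratified log-rank screen.

    For each candidate, the high-expression group (fold change >=
    ``2**lfc_threshold`` over baseline) is compared with all other
    samples.  A gene is selected when the log-rank p is below ``alpha``
    and, by default, the high group is the worse-surviving one
    (observed > expected events in the high group).  Candidates whose
    high group is empty (or covers the whole cohort) are reported
    untestable.

    Returns a DataFrame indexed by gene with columns ``n_high``,
    ``logrank_chi2``, ``p``, ``worse_in_high``, ``selected``,
    ``testable``.
    """
    rows = []
    for gene in candidate_genes:
        high = stratify_by_expression(cohort, gene, lfc_threshold)
        n_high = int(high.sum())
        if n_high == 0 or n_high == len(cohort):
            rows.append((gene, n_high, np.nan, np.nan, False, False, False))
            continue
        t_h, e_h = cohort.time[high], cohort.event[high]
        t_l, e_l = cohort.time[~high], cohort.event[~high]
        chi2, p = logrank_test(t_h, e_h, t_l, e_l)
        worse = _observed_minus_expected(t_h, e_h, t_l, e_l) > 0
        selected = bool(p < alpha and (worse or not enforce_direction))
        rows.append((gene, n_high, chi2, p, worse, selected, True))
    return pd.DataFrame(
        rows,
        columns=["gene", "n_high", "logrank_chi2", "p", "worse_in_high",
                 "selected", "testable"],
    ).set_index("gene")
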