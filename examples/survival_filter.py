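"""Expression-stratified survival filter on candidate genes.

Simulates a 300-patient cohort in which one candidate gene carries a
hazard ratio of 3 for its high-expression samples, then screens the
candidates: samples at >= 2x baseline expression form the high group,
Kaplan-Meier curves are compared with a log-rank test, and only genes
whose high group fares *worse* pass.
"""

from oncoscreen import (SimulationConfig, kaplan_meier, simulate_survival,
                        stratify_by_expression, survival_screen)

cfg = SimulationConfig(seed=7, survival_cohort_size=300,
                       survival_hazard_ratio=3.0, censoring_fraction=0.2)
candidates = ["RBP0001", "RBP0002", "RBP0003", "RBP0004"]
cohort, truth = simulate_survival(cfg, candidates, planted_genes={"RBP0001"})

table = survival_screen(cohort, candidates, lfc_threshold=1.0, alpha=0.05)
print(table.round(4))

high = stratify_by_expression(cohort, "RBP0001")
km_high = kaplan_meier(cohort.time[high], cohort.event[high])
km_low = kaplan_meier(cohort.time[~high], cohort.event[~high])
t = 365.0
print(f"\nRBP0001 one-year survival: high group {km_high.survival_at(t):.2f} "
      f"vs others {km_low.survival_at(t):.2f}")
print("-> the planted gene is selected (p < 0.05 with the high group dying "
      "faster); null genes are not.")
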