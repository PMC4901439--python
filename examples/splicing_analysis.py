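"""Differential splicing from junction counts.

Simulates five event types with triplicate junction counts in control
and knockdown conditions (a fraction of events carries a planted dPSI of
0.3), estimates PSI, runs the pooled likelihood-ratio test, applies the
reporting gates (|dPSI| > 0.1, FDR < 0.05) and summarises per type.
"""

from oncoscreen import (SimulationConfig, apply_splicing_gates,
                        differential_splicing, simulate_splicing_events,
                        summarize_by_type)

cfg = SimulationConfig(seed=3, n_events_per_type=300, event_depth=200.0,
                       planted_dpsi=0.3)
events, truth, _ = simulate_splicing_events(cfg)

table = differential_splicing(events)              # control vs knockdown
gated = apply_splicing_gates(table, dpsi_min=0.1, fdr_alpha=0.05)
print(summarize_by_type(gated))

regulated = {e for e, lab in truth.regulation.items() if lab != "unaffected"}
called = set(gated.index[gated["significant"]])
tp = len(called & regulated)
print(f"\nplanted regulated events: {len(regulated)}; called significant: "
      f"{len(called)}; recovered: {tp}")
print("-> n_significant per type counts events passing both gates; most "
      "calls coincide with the planted dPSI and false calls stay near the "
      "FDR target.")
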