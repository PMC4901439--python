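"""Sequence characterisation of regulated exons and introns.

After calling differential splicing on simulated events, classifies each
exon/intron as constitutive or alternative from control PSI, compares
affected proportions per class, and contrasts the two regulation
directions on length, GC content and PWM splice-site strength.
"""

import pandas as pd

from oncoscreen import (SimulationConfig, apply_splicing_gates,
                        differential_splicing, simulate_splicing_events)
from oncoscreen.pipeline import characterize_events

pd.set_option("display.width", 160)

cfg = SimulationConfig(seed=12)
events, truth, genome = simulate_splicing_events(cfg)
gated = apply_splicing_gates(differential_splicing(events))
res = characterize_events(events, gated, genome)

for etype, label in (("SE", "cassette exons"), ("RI", "retained introns")):
    block = res[etype]
    prop = block["affected_proportions"]
    print(f"\n== {label} ==")
    print(f"affected: {prop['proportion_constitutive']:.1%} of constitutive "
          f"vs {prop['proportion_alternative']:.1%} of alternative "
          f"(proportion-test p = {prop['p']:.2g})")
    print(pd.DataFrame(block["group_comparison"]).set_index("feature").round(3))

print("\n-> alternative segments are hit far more often than constitutive "
      "ones; knockdown-excluded exons are shorter, GC-poorer and carry "
      "stronger splice sites, knockdown-retained introns are shorter and "
      "GC-richer with no splice-site difference (the planted null).")
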