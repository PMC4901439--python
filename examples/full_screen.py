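"""The whole candidate funnel in one call.

Runs simulation -> DE in two contexts -> overlap -> survival filter ->
alteration/miRNA enrichment -> differential splicing -> characterisation
with a single seed, and prints the funnel counts from the JSON report.
"""

import json

from oncoscreen import ScreenConfig, run_screen

cfg = ScreenConfig(seed=1, n_iter=5000,
                   simulation=dict(n_genes=600, n_rbp_genes=600,
                                   samples_per_group=10,
                                   n_events_per_type=150))
report = run_screen(cfg)

print("funnel:", json.dumps(report["funnel"], indent=1))
print("overlap p:", f"{report['stages']['overlap']['p_hypergeometric']:.3g}")
print("alteration permutation p:",
      report["stages"]["alterations"]["permutation_p"])
print("top miRNA:", report["stages"]["alterations"]["top_mirna"],
      f"(p = {report['stages']['alterations']['top_mirna_p']:.3g})")
print("-> counts shrink along the funnel (up in each context -> shared -> "
      "survival-associated); the enriched miRNA and the unremarkable "
      "alteration burden mirror the screen's regulatory analysis.")
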