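# oncoscreen

An integrative screen for RNA-binding proteins (RBPs) with oncogenic
potential, plus the downstream differential-splicing analysis, as a
tested, reusable Python library. It targets computational biologists who
want to run — or stress-test — a multi-stage candidate funnel of the kind
used in glioblastoma transcriptomics:

1. **Differential expression in two tumor contexts** (bulk tumor vs.
   normal tissue; stem-cell lines vs. normal progenitors) with a
   negative-binomial model and the gates |log2FC| ≥ 1, BH-adjusted
   p < 0.05.
2. **Overlap test**: the two upregulated sets are intersected and the
   overlap assessed with an upper-tail hypergeometric test against the
   RBP catalog universe (1542 genes by default).
3. **Survival filter**: per candidate, samples with expression ≥ 2× a
   baseline form the high group; Kaplan–Meier curves are compared with a
   log-rank test and only genes whose high group fares *worse* pass
   (p < 0.05).
4. **Alteration / miRNA nulls**: the candidates' mutation/CNA burden is
   compared against 100,000 random same-size RBP sets (add-one empirical
   p), and miRNA targeting is scored per-miRNA with hypergeometric tests.
5. **Differential splicing**: percent spliced in from junction counts,
   PSI = (I/lI) / (I/lI + S/lS), for the five event classes
   (SE, MXE, A5SS, A3SS, RI); a pooled binomial likelihood-ratio test per
   event; gates |ΔPSI| > 0.1, FDR < 0.05.
6. **Exon/intron characterisation**: constitutive (control PSI = 1 for
   exons, 0 for introns) vs. alternative classes, affected-proportion
   tests, and length / GC% / PWM splice-site-strength comparisons between
   regulation directions.

Because the original tumor datasets are access-controlled, the package
ships a first-class synthetic-data generator (`oncoscreen.simulate`) that
emulates every input with known ground truth — planted fold changes,
hazard ratios, ΔPSI and sequence-feature trends — so each stage's
calibration and power are testable end to end.

## Worked example

`examples/survival_filter.py` simulates a 300-patient cohort in which
`RBP0001` carries a hazard ratio of 3 for its high-expression samples and
screens four candidates:

```
         n_high  logrank_chi2       p  worse_in_high  selected  testable
gene
RBP0001      75       80.6919  0.0000           True      True      True
RBP0002      35        0.0001  0.9906          False     False      True
RBP0003      44        0.1012  0.7504           True     False      True
RBP0004      34        0.8744  0.3497           True     False      True

RBP0001 one-year survival: high group 0.10 vs others 0.54
```

`n_high` counts samples at ≥ 2× baseline expression; the planted gene's
high group has a log-rank chi-square of 80.7 (p ≈ 0) and clearly worse
one-year survival (10% vs 54%), so it is selected; the three null genes
are not. The other scripts in `examples/` walk through the expression
screen with the overlap test, the splicing calls with per-type summaries,
the sequence characterisation, and the full funnel (`full_screen.py`).

A thin CLI mirrors the library:

```bash
oncoscreen simulate --seed 1 --out-dir sim/
oncoscreen de --counts sim/counts.tsv --out de.tsv
oncoscreen splice --events sim/events.tsv --out calls.tsv
oncoscreen run --seed 1 --out-dir screen_out/
```

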