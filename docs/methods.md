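# Methods

This note documents the statistical models behind each stage, the
synthetic-data generator that stands in for the original tumor datasets,
the numerical choices, and what the tests do and do not establish.

## Differential expression

Counts are modelled as negative binomial with mean μ and variance
μ + αμ² (α = 0 degenerates to Poisson). Library sizes are normalised
with median-of-ratios size factors: for each sample, the median over
genes with all-positive counts of count / geometric-mean. The median is
taken in linear space; tools that interpolate in log space differ by
well under 1% at even gene counts (a cross-check against pydeseq2 is in
the test suite).

The test statistic is a Wald z on the difference of log normalised group
means. By the delta method, Var(log ȳ_g) ≈ (1/(n_g μ_g)) · mean(1/s) +
α/n_g with a single pooled dispersion α̂. α̂ is a method-of-moments
estimate from *within-group* variability (so planted or real
between-group effects do not inflate it), averaged across genes with the
per-gene estimates floored at zero. The flooring biases α̂ slightly
upward, which is mildly conservative. With thousands of genes the pooled
estimate is precise and the normal reference is well calibrated even at
5 vs 5 samples (measured type-I ≈ 0.048 at nominal 0.05; see
`tests/test_acceptance.py`). Genes observed in only one group fall back
to a t-test on log-transformed normalised counts; all-zero genes are
reported untested. Displayed log2 fold changes use a 0.5 pseudocount.

No dispersion shrinkage or empirical-Bayes moderation is attempted: the
screen's contribution surface is its gates (|log2FC| ≥ 1 inclusive,
BH-adjusted p < 0.05 exclusive) and the two-context intersection, not
the internals of any particular DE engine. A `log_t` engine (two-sample
t on log counts) is available for intensity-like data.

Multiple testing uses Benjamini–Hochberg step-up adjustment
(statsmodels). The overlap of the two contexts' upregulated sets is
tested with an upper-tail hypergeometric p, P(X ≥ k), with the
universe defaulting to the 1542-gene RBP catalog; whether the universe
should instead be the platform-expressed subset is a judgement call, so
the size is a parameter.

## Survival filter

Samples whose expression is at least 2^t times baseline (t = 1 by
default, boundary inclusive) form the high group; baseline is the mean
over user-designated reference samples when available, else the cohort
mean (the registry convention the screen relies on is not fully
specified, so the default is explicit and overridable). Kaplan–Meier
estimation and the Mantel–Haenszel log-rank test delegate to lifelines;
p-values come from a 1-df chi-square without continuity correction.
Selection additionally requires the high group to be the
worse-surviving one, judged by the sign of observed-minus-expected
events in the high group over the shared risk sets (equivalent to an
estimated hazard ratio above 1); a flag disables the direction
requirement. No multiple-testing correction is applied across candidate
genes at this stage, matching the screen's design.

## Alteration and miRNA nulls

The alteration statistic is the fraction of samples with at least one
altered gene in the set (an aggregate pair-count statistic is available
by flag; the summary-level sample fraction is the default because that
is the quantity the screen reports). The null draws uniform same-size
subsets of the universe without replacement, independently across
iterations, and the empirical p is the add-one estimator
(r + 1)/(B + 1), which cannot reach zero — appropriate for a
simulation-based p. miRNA-target enrichment is a per-miRNA upper-tail
hypergeometric test of target overlap with the candidate set.

## Differential splicing

PSI is the effective-length-weighted inclusion fraction
(I/lI) / (I/lI + S/lS). Junction-count effective lengths default to
lI = 2, lS = 1 for SE/A5SS/A3SS (two inclusion junctions vs one
skipping junction), lI = lS = 2 for MXE, and lI = 2, lS = 1 for RI
(two boundary-spanning classes vs one excising junction); the
read-length-dependent values a specific aligner would produce are not
recoverable in general, so the defaults are overridable per event.

The test pools replicate counts within condition and compares a
shared-proportion binomial model against separate per-condition
proportions with a 1-df likelihood-ratio (G) statistic on the 2×2
inclusion/skipping table. Under binomial sampling this is calibrated at
the simulated depths (measured type-I ≈ 0.05 at depth 200 with
triplicates). A beta-binomial variant with a common overdispersion ρ,
fitted by Nelder–Mead on logit-transformed parameters, is available
behind a flag for data with genuine between-replicate heterogeneity; the
hierarchical paired models of dedicated splicing packages are
deliberately out of scope. ΔPSI is the difference of mean replicate PSI
(condition 1 − condition 2; with the default (control, knockdown)
orientation positive ΔPSI means "more included in control"). Events at
a PSI boundary in both conditions carry no sampling variance, so a
null-calibration experiment should use interior-PSI events
(`alternative_fraction=1`); boundary events simply never reject.

BH adjustment runs within each event type by default, since gated
counts are reported per type; a global scope is available. Gates are
|ΔPSI| strictly greater than 0.1 and FDR < 0.05.

## Exon/intron characterisation

Constitutive events have control PSI = 1 (exon classes) or 0 (retained
introns). Estimated PSI on finite counts rarely hits the boundary
exactly, so the default applies a tolerance ε = 0.005 to the mean
control PSI; an exact-boundary mode and a per-replicate ("all") mode
exist. Affected proportions per class are compared with the 2×2
chi-square test with continuity correction (the R `prop.test`
convention — which variant the original analysis used is not stated).

Splice sites are scored with a position-weight-matrix log-odds model in
bits over the canonical windows: donor 9-mer (3 exonic + 6 intronic),
acceptor 23-mer (20 intronic + 3 exonic), extracted strand-aware
(reverse-complemented on minus-strand events). The scorer trains
per-position frequencies with a pseudocount from any foreground site
collection against a background site set or composition. The full
maximum-entropy model with published parameter tables is out of scope:
the characterisation uses scores only inside rank-based group
comparisons, for which any calibrated monotone scorer of the same
windows suffices, and the interface accepts a drop-in replacement. In
the pipeline the models are trained per event type on the constitutive
events' sites — a biologically sensible "canonical site" foreground
that requires no external data.

Feature comparisons between regulation directions use two-sided
Wilcoxon rank-sum tests: exact when both groups have ≤ 25 tie-free
observations, otherwise the tie-corrected normal approximation with
continuity correction.

## Synthetic data generator

One master seed drives every stage through independent, stage-labelled
substreams (`SeedSequence([seed, crc32(stage)])`), so identical
configurations reproduce byte-identical outputs and stages can be
re-run in isolation.

* **Counts**: per-gene lognormal baseline proportions (σ = 1), lognormal
  per-sample depth (mean 5×10⁵ reads, σ = 0.15), NB dispersion α = 0.05 —
  conventional bulk-RNA-seq values; the original libraries' depth and
  dispersion are not published, so these are conditions, not
  reconstructions. DE genes receive multiplicative 2^±lfc shifts
  (default lfc = 2).
* **Survival**: exponential event times (constant hazard; closed-form
  medians ln2/λ make oracle checks exact), baseline median 400 days, a
  high-expression arm comprising 25% of a 300-patient cohort at the
  configured hazard ratio (default 3). The arm fraction must stay below
  one half: with a cohort-mean baseline, a 2× stratification threshold is
  unreachable when half the cohort is at 4×. Censoring is administrative:
  C ~ U(0, τ) with τ solved from (1 − e^{−λτ})/(λτ) = target fraction.
  Planted-gene expression jitter (lognormal σ = 0.02) is kept far below
  the stratification margin so the planted arm is exactly the high group.
* **Alterations**: independent Bernoulli entries at a 1% background rate
  (≈ 2.7 altered samples per gene at n = 273), optionally elevated on a
  target set.
* **Splicing events**: 600 events per type, half constitutive (PSI at
  the boundary) and half alternative (uniform interior PSI). Regulated
  events are drawn at 25% among alternative vs 6% among constitutive
  events — reproducing the differential susceptibility the
  characterisation stage measures — with the knockdown direction
  (exon exclusion, intron retention) taken 70% of the time and forced
  for constitutive events, where only one direction can leave the
  boundary. Planted ΔPSI defaults to 0.3; values leaving [0,1] are
  clipped with a logged warning. Replicate counts are binomial at
  Poisson(depth 200) totals around the effective-length-weighted
  inclusion probability, three replicates per arm.
* **Sequence context**: one synthetic chromosome per event type; each
  event contributes flank–segment–flank with i.i.d. bases at a planted
  GC, boundary windows overwritten with site k-mers sampled per-position
  from a consensus-biased distribution. The planted trends are
  qualitative matches to the screen's findings with magnitudes chosen
  a priori for statistical power at the simulated group sizes
  (~65 vs ~28 regulated exons per run): exon length medians 100 vs
  300 nt (knockdown-excluded vs control-excluded; lognormal σ = 0.45),
  GC 42 vs 54% (σ = 5), site consensus bias 0.85 vs 0 (uniform); intron
  medians 400 vs 1400 nt, GC 58 vs 44%, and *no* site-strength
  difference (the planted null). All generated events sit on the plus
  strand; minus-strand window extraction is exercised by hand-built
  fixtures instead.

### What passing tests do and do not show

The generator draws independent genes, independent samples, binomial
junction counts and i.i.d. sequence; real data have correlated genes,
batch structure, overdispersed junction counts, GC/mappability biases
and non-exponential hazards. Calibration and recovery on these
simulations therefore validate the implementations and their gates
under their stated models — they do not certify performance on real
tumor cohorts, and the published external-data tallies (candidate
counts, event counts, printed medians) are intentionally not
reproduction targets.

## Numerical choices and degenerate inputs

* Hypergeometric tails use exact survival functions; k = 0 returns 1.
* BH rejects NaN inputs rather than propagating them.
* Log-rank with zero events in both groups returns (0, 1) with a
  warning; a candidate whose high group is empty (or the whole cohort)
  is reported untestable and excluded.
* PSI with zero total counts is NaN ("unquantifiable"); events
  quantifiable in only one condition are reported untested.
* G-statistic cells with zero observations contribute zero; a fully
  degenerate table gives statistic 0, p = 1.
* PWM training demands a positive pseudocount whenever a base is
  unobserved, preventing infinite scores; scoring skips non-ACGT
  positions with a warning.
* Coordinates are 0-based half-open everywhere internally and in BED
  output; GC is computed strand-independently with ambiguous bases
  removed from the denominator.

## Problem sizes

Default analyses run at the screen's scale (1542 genes, 600 events per
type, 300-patient cohorts). Calibration experiments in the tests and in
`scripts/acceptance.py` use 5000-gene null matrices (20 replicates),
1000 log-rank replicates, 100,000 permutation iterations, 500-event
power batches and 10–20 characterisation replicates — sizes at which
Monte-Carlo standard errors are small relative to the tolerances being
checked.
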