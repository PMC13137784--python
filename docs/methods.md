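# Methods

`stingsig` re-implements, as a tested pipeline, the derivation of a
stimulus-driven gene-module signature from time-course RNA-seq counts and
the downstream use of that signature to score, diagnose and stratify
samples. This note documents the models, the numerical choices, and what
the synthetic designs do and do not establish.

## Statistical primitives

All inferential primitives are implemented from first principles so every
stage shares one set of conventions; SciPy supplies only special functions
(log-gamma, t/F/normal tails) and serves as an independent oracle in tests.

- **Fisher's exact 2×2 test** conditions on both margins (hypergeometric
  law). The two-sided p-value is the minimum-likelihood definition: the sum
  of all outcome probabilities not exceeding the observed one, compared with
  relative tolerance 1e-12. The reported odds ratio is the sample OR
  `ad/bc`; the Haldane–Anscombe +0.5 correction is applied to all cells
  only when some cell is zero, and only for the OR, never for the p-value.
- **Benjamini–Hochberg** adjustment is the standard step-up
  `q_(i) = min_{j≥i} m·p_(j)/j`, clipped at 1. (Note: BH is *not*
  idempotent — re-adjusting `[1.0, 0.5]` yields `[1.0, 1.0]` — so only
  domination, clipping and order preservation are asserted as invariants.)
- **Wilcoxon rank-sum** uses exact enumeration of all rank assignments when
  the combined sample size is ≤ 12 and the data are tie-free, otherwise the
  normal approximation with tie and continuity corrections. The effect size
  is the rank-biserial correlation.
- **AUROC** is the Mann–Whitney statistic with ties counted ½; it is
  invariant under strictly increasing score transforms.
- All tests are two-tailed by default; the pipeline uses one-sided tests
  only where the question is directional (promoter-target enrichment:
  "greater"; antagonist suppression: "less").

## Normalization

TMM (trimmed mean of M-values) is re-implemented rather than called: the
reference sample is the one whose 75th-percentile count proportion is
closest to the mean of those quantiles; genes zero in either member of a
pair are dropped; M-values are trimmed 30% per tail and A-values 5% per
tail (the method's established defaults); the factor is the
inverse-asymptotic-variance weighted mean of the surviving M values, and
factors are rescaled to geometric mean 1. Expression units downstream are
`log2(1 + CPM)` on TMM-effective library sizes, so a zero count maps to
exactly 0 — the prior count of 1 is a choice, as is everything about the
transform. A frozen fixture computed with edgeR's `calcNormFactors` pins
the implementation to the reference behavior.

## Module discovery

For each gene, ordinary least-squares polynomials of degree 1–3 in hours
post-stimulation are fitted to the treated arm at replicate level; the
degree with the highest adjusted R² wins (ties within 1e-12 go to the
lowest degree) and significance is the overall F test of the chosen model,
gated at BH FDR < 10%. **A calibration caveat:** choosing the best of
three nested models and then quoting the chosen model's F-test p-value is
anti-conservative under the null — in simulation the probability of any
BH rejection on a fully null 2,000-gene course is ≈ 0.16–0.23 instead of
the nominal 0.10. The procedure is kept as specified because it is the
procedure under study; users wanting strict calibration should pre-commit
a degree.

Selected genes are clustered on the Pearson correlation of their z-scored
per-timepoint mean profiles: edges where r ≥ 0.7 (weight = r), Markov
clustering with self-loops, expansion power 2, inflation 2.0 (the method's
default), pruning at 1e-5, convergence when the maximum entry change drops
below 1e-8 or after 100 iterations. Nodes claimed by several attractor
rows go to the largest cluster (ties to the cluster with the
lexicographically smallest member id); unassigned nodes become singletons,
which makes the partition invariant to gene input order.

Refinement applies the ≥ 50-gene size filter to raw clusters first, then
removes genes lacking any within-module protein-interaction edge with
score ≥ 400, and finally re-checks the size floor so every surviving
module respects it. The size-then-interaction order is one of two
defensible readings of the procedure; the alternative order is a flag away
in the code.

## TF enrichment and the core signature

Core promoters are `[tss−500, tss+500)` and proximal promoters
`[tss−1000, tss+1000)` (0-based half-open, clipped at zero); minus-strand
genes use the 3′-most genomic coordinate of their span as the TSS, and
genes with several TSS records use the 5′-most in gene orientation. A gene
is a TF target if any binding site overlaps the window by at least 1 bp on
the same chromosome, ignoring site strand. Per module and window kind,
each TF gets a one-sided (greater) Fisher test of the 2×2
(in-module vs background-only) × (target vs non-target) table, with the
expressed genes as background and BH adjustment across TFs within each
window kind.

Differential induction is a negative-binomial exact test after TMM:
libraries are equalized by scaling counts to the geometric-mean effective
library size (with rounding — a simplification of quantile adjustment),
group sums are aggregated NB variables with a common dispersion, and
conditional on the total the split follows a beta-binomial law (binomial
at dispersion 0). The two-sided p sums all conditional splits no more
likely than the observed one. The common dispersion maximizes the summed
conditional log-likelihood given per-gene group totals, via deterministic
golden-section search over log-dispersion in [1e-6, 10]. Fold changes use
TMM-normalized group means with a prior of 0.125 per group.

The **core signature** is the three-way intersection: focal-module genes
that are targets of the module's top-enriched TF (core *or* proximal
window) and significantly induced (q < 0.05, LFC > 0) in treated vs
control with all post-stimulation timepoints pooled as replicates. The
focal module is the final module with the strongest mean treated-vs-control
log fold change, mirroring the choice of the most disease-induced module.
Which criterion excluded each non-core module gene is recorded.

## Scoring and diagnostics

The signature score of a sample is the median expression of the signature
genes — median log2-CPM within an experiment, or the median of per-gene
cohort z-scores for cross-cohort use (zero-variance genes dropped). A
sample is called pathway-activated when the Pearson correlation of its
core-gene induction profile with the reference stimulation profile exceeds
0.6 strictly. A patient responds to the antagonist when the one-sided
rank-sum test of core-gene fold changes against all other genes' fold
changes survives BH at q < 0.05 across patients and the median core fold
change is negative. Gene responsiveness is ranked by the R² of regressing
per-patient treatment fold change on baseline expression (zero-variance
baselines get R² = 0 and rank last). PCA variance fractions come from the
singular values of the gene-centered expression matrix.

## Synthetic data

The generator plants the exact structure the pipeline assumes, with all
randomness flowing from one seed through named streams (same seed ⇒
byte-identical files):

- Gene baseline abundances are lognormal in CPM units
  (ln-mean 4.5, ln-sd 1.0 — a deeply covered, pre-filtered transcriptome),
  gene dispersions lognormal (ln-mean −4.0, ln-sd 0.5; cell-line-replicate
  biological CV ≈ 0.14), library sizes lognormal (ln-mean 14.5 ≈ 2M,
  ln-sd 0.2). Counts are gamma-Poisson draws on a mean that includes
  log2-scale residual noise (default sd 0.3).
- The default time course is 0–24 h at 8 timepoints with duplicates, a
  treated and a paired control arm sharing all gene-level parameters.
  Modules follow logistic activation curves (steepness 0.25 h) whose
  midpoints sit in the interior inter-timepoint gaps, and alternate
  induced/repressed direction. Both choices are deliberate: a transition
  on the first or last observation leaves a cubic polynomial little signal
  variance to detect, and with ≤ 8 timepoints five same-sign step profiles
  cannot all stay below the 0.7 co-expression threshold (adjacent steps
  correlate at ≈ 0.71), whereas real stimulus-response programs do contain
  both induced and repressed waves.
- A core subset (default 30%) of each *induced* module is planted as
  TF-targeted-and-induced; each induced module gets its own TF whose
  binding sites cover the cores plus a 5% background rate, alongside decoy
  TFs with background targets only. Genes tile one synthetic chromosome
  every 10 kb on alternating strands. PPI edges are Bernoulli (0.3 within
  modules with scores 400–999, 0.002 otherwise with scores 150–399).
- Cohort, paired-antagonist and dose-ladder designs reuse the same gene
  pool: cases shift core genes by N(effect, effect/4) on log2; responder
  patients lose 0.8× their baseline activation (drawn as
  effect × U(0.3, 1.7)) in the treated arm, so suppression magnitude
  anticorrelates with baseline activity; dose ladders scale the module
  effect linearly with dose.

What passing the synthetic benchmarks does **not** show: robustness to
batch effects, outlier samples, unmodeled covariates, length or GC biases,
annotation errors, or modules whose temporal profiles genuinely overlap —
none of which the generator emulates.

## Benchmark scales and metrics

The recovery benchmarks (shared by the test suite and
`scripts/acceptance.py`) run at the scale each question needs while
remaining desk-size: 2,000 genes; 50 seeds for null calibrations, 10 for
end-to-end recovery, 20 elsewhere. Module recovery is measured as the
adjusted Rand index between the final-module partition and the planted
assignment over the genes the final modules contain (background genes form
their own class); genes the screen missed are outside the discovered
partition and are not scored. Core recovery is the Jaccard index between
the derived core and the planted core of the best-matching module.

## Known limitations

- The common dispersion is a single shared value; tagwise or trended
  dispersion is out of scope, so genes with atypical dispersion are tested
  slightly liberally or conservatively.
- Library equalization by geometric-mean scaling with rounding is an
  approximation; with strongly unequal library sizes the exact-test
  p-values shift slightly relative to quantile-based equalization.
- The regression screen's selection-induced anti-conservativeness (above)
  is a property of the published procedure, preserved by design.
- The enrichment background is the expressed-gene universe of the count
  matrix; no correction for promoter mappability or CpG content is
  attempted.
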