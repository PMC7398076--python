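# Methods

`dabench` evaluates differential-abundance (DA) methods for sparse microbiome
count data on five axes: goodness of fit of candidate count models, type-I
error on mock comparisons, concordance at the top between ranked result
lists, directional enrichment of expected taxa, and power on parametric
simulations.  This note records the models, the numerical choices, and what
the synthetic data do and do not emulate.

## Data model

The universal input is a features-by-samples matrix of non-negative integer
read counts `y_fj` with library sizes `lib_j = Σ_f y_fj`, plus per-sample
metadata (subject, group, sequencing center) and per-feature annotations
(taxonomy, genus-level metabolism).  Missing metadata values are coded with
the sentinel `"absent"` and excluded from enrichment denominators, like the
`unassigned` metabolism class.

Filtering follows the standard preprocessing for this kind of data and uses
strict inequalities throughout: samples with `lib > min_libsize` are kept,
then features with `count > min_count` (default 10) in more than
`min_samples` (default 1) samples.  An off-by-one here changes every
downstream count, which is why the strictness is part of the contract and
covered by tests.  Rarefaction draws a multivariate hypergeometric sample
per column (subsampling of physical reads without replacement), so depths
are exact and no cell can exceed its original count.

## Normalizations

* **TSS** — the library size itself.
* **TMM** — trimmed mean of M-values relative to a reference sample (the one
  whose upper quartile of scaled counts is closest to the mean upper
  quartile).  Log-ratios are doubly trimmed (30% on M, 5% on A, each tail)
  and combined with inverse-variance weights; factors are rescaled to
  geometric mean 1.  The trim constants are the method's standard values,
  exposed as module constants.
* **poscounts** — median-of-ratios size factors with the per-feature
  reference `g_f = (Π_{j: y>0} y_fj)^{1/n}` (geometric mean of the positive
  counts with exponent 1/n over all samples).  Zero ratios are *included* in
  the median; on zero-free tables this reduces exactly to the classic
  median-of-ratios factor (tested).
* **CSS** — cumulative sum scaling: `s_j` is the sum of sample j's counts up
  to a data-driven quantile.  The quantile search computes, along a 0.01
  grid, the median absolute deviation of the per-sample positive-count
  quantiles around their mean profile, and stops at the first quantile
  (≥ 0.5) whose deviation grows by more than 10% relative to the previous
  grid point; if no such point exists the fallback quantile is 0.5.  This
  instability rule is this package's formulation of the idea; the threshold
  is a documented constant with an override.

Log-scale transforms: `log2_cpm`, `log2_median_libsize` (counts rescaled by
the median library size), CLR on pseudocounted relative abundances (each
sample's CLR vector sums to zero), and the two CSS offset conventions —
`log2(s/1000 + 1)` ("count per thousand") and `log2(s/median(s))`.  The
median-rescaled CSS offset deliberately has no `+1`, matching the original
formulation of that variant.

## Candidate distributions and goodness of fit

Five models are fit per feature under an intercept-only design (homogeneous
samples):

* **NB** — negative binomial on counts with log library-size (or
  normalization) offsets; dispersion `phi` per feature (ML, golden-section
  on log `phi`) or common (pooled 1-D optimization).  `P(0) = (1 +
  phi·mu)^(-1/phi)`, with the Poisson limit `exp(-mu)` as `phi → 0`.
* **ZINB** — structural zeros with probability `pi_f` mixed with NB; fit by
  EM with a common dispersion.  With an intercept-only mean, no latent
  factors and a common dispersion, the ridge penalty of the penalized
  formulation vanishes identically, so the `epsilon` argument (kept for
  interface stability, default 1e10; 1e14 when fitting simulation
  templates) has no effect here.  EM stops on relative log-likelihood
  change < 1e-6 or 60 iterations; near-convergence at the cap (< 1e-4) is
  accepted, otherwise features are flagged and excluded from RMSEs.
* **ZIG** — zero-inflated Gaussian on `log2(count+1)` with CSS offsets.  The
  mixing probability is a logistic function of (standardized) log library
  size shared across features, so the model-implied zero probability is
  constant across features — which is exactly why this model underestimates
  the zero fraction of sparse features and overestimates it for dense ones.
* **HURDLE** — logistic detection model with the sample detection rate (CDR,
  the fraction of features detected in a sample) as covariate, plus a
  Gaussian on the positive cells of the chosen log scale
  (`log2_median_libsize` by default, `log2_cpm` available).
* **DM** — Dirichlet-multinomial concentrations by the standard fixed-point
  iteration; `P(0)` from the beta-binomial marginal
  `Γ(α0)Γ(α0−α_f+n_j) / (Γ(α0+n_j)Γ(α0−α_f))` averaged over samples
  (log-gamma arithmetic; the marginal is not part of the original model
  description, so the formula is documented here).

GOF compares, per feature, the estimated mean against the observed mean on
the `log2(mean + 1)` scale (Gaussian-model fitted values are already on the
log scale and enter directly — this preserves the visible Jensen-gap
underestimation of the log-scale models) and the model zero probability
against the observed zero frequency (ZPD).  Both are summarized as RMSE
across converged features; whether the observed mean is `log2(mean(y)+1)`
(default) or `mean(log2(y+1))` is a flag.  Models are ranked 1..K per
dataset by RMSE with mean ranks for ties and averaged across datasets.

## DA methods

Thirteen built-ins cover the families compared in DA benchmarking (see the
catalog table in `dabench.methods`).  Design: intercept + two-level group;
coefficients are signed group2 vs group1 with the lexicographically first
label as reference.  All methods are vectorized across features; stochastic
ones take a seed.  Shared primitives:

* **BH adjustment** operates on the present p values only (m = number
  tested); missing entries stay missing and rank last.
* **Empirical-Bayes moderation** estimates the prior (d0, s0²) by moment
  matching on log s² (trigamma inversion by Newton); all-equal variances
  legally give d0 = ∞ and collapse to s0².
* **ZINB observational weights** are the posterior probability that a count
  came from the NB component: 1 for positives,
  `(1−pi)·NB0 / (pi + (1−pi)·NB0)` at zeros.

Method internals not pinned by the original descriptions, chosen here and
exposed as options: NB-GLM dispersions are per-feature ML shrunk toward a
lowess mean-dispersion trend with prior df 10 (the robust variant uses the
raw per-feature ML values with a quasi-likelihood F test, which reproduces
the liberal behavior of that family); the Monte-Carlo Dirichlet method uses
128 draws with arithmetic-mean aggregation of per-draw rank-sum p values
and an interquartile-log-ratio (iqlr) CLR denominator; the rank-sum method
tests Seurat-style log-normalized data (`log1p(y/lib·1e4)`) with optional
prevalence (< 0.1) and effect (|logFC| < 0.25, measured as the difference
of group means of the log-normalized data) prefilters — note that the
effect prefilter selects on the observed difference and therefore inflates
the FPR *among tested features* on null data; calibration analyses should
disable it (`prevalence_filter=None, logfc_filter=None`).  The beta-binomial
regression (logit links on mean and dispersion) is optimized by L-BFGS with
an analytic digamma gradient and a derivative-free polish on line-search
failures near the boundary; Wald errors come from a finite-difference
observed information.  The hurdle test sums the detection-logistic and
positive-Gaussian likelihood-ratio components (chi-square, df 2).  The
ZINB-weighted NB GLM uses an F test with residual df `Σw − p` — an
approximation, as the exact adjustment is not fully specified in the
literature this follows.

## Evaluation engines

**Type I error.**  Balanced mock labelings (group 1 gets ⌈n/2⌉ samples; all
B labelings distinct when combinatorially possible) on a presumed-null
table.  Per mock and method: two-sided KS distance of the raw p values to
U(0,1) and the fraction below each nominal alpha (0.01, 0.05, 0.1).  The
averaged qq curve takes quantile-wise means across mocks.  Failures of a
method on a mock are tallied and excluded for that method only.

**Concordance.**  CAT: `C_i = |top_i(L) ∩ top_i(M)| / i`, i = 1..R (default
R = 100), summarized by the rectangle-rule AUC.  Ranked lists are made
strict orders by the tie-break (raw p, |statistic| descending, feature id);
methods without p values rank by importance score.  When fewer than R
features are rankable the curve is reported as missing beyond the universe
size and the AUC averages the available ranks, with a flag.  The split
engine halves the samples stratified by group (after keeping one sample per
subject, first-after-seeded-shuffle); WMC is a method against itself across
halves, BMC two methods within a half averaged over the two halves, both
averaged over splits (subset averaging last).

**Enrichment.**  DA set = adjusted p < 0.1 (or the top 10% of the ranking
for importance-only methods); direction from the coefficient sign.  Six
one-sided Fisher exact tests ({aerobic, anaerobic, facultative} × {UP,
DOWN}) on 2×2 tables over the annotated universe; log odds ratios use the
Haldane-Anscombe +0.5 per cell (+1 per cell for the variance).  The TP−FP
curve counts putative true positives (aerobic-UP plus anaerobic-DOWN) minus
putative false positives within the top 1..20% of the ranking.  Mutual
findings count features called in a given direction by at least k methods;
picking one representative method per normalization is left to the caller
via the catalog labels.

## Simulator

Templates hold per-feature relative means `r_f` (sum 1), a common NB
dispersion, optional per-feature zero-inflation probabilities, and an
empirical library-size pool (resampled with replacement — this preserves
the 16S-vs-WMS depth contrast).  Templates come from real tables (NB or
ZINB fits as above) or from the two bundled synthetic generators:

* **16S-like**: F = 900 by default, log-normal composition (σ = 2.6),
  common dispersion 1.2, target depths around 5×10³ — realized zero
  fractions fall in the 0.55–0.83 band typical of amplicon data.
* **WMS-like**: ZINB with Beta(1.2, 2) zero inflation and target depths
  around 5×10⁶ (floor 2×10⁶, so that realized library sizes stay above 10⁶
  after the zero-inflation mass loss) — realized zero fractions around
  0.4–0.7 despite the depth.

DA injection flags `round(p·F)` features uniformly.  Without compensation,
half are multiplied by the fold effect and the rest divided by it, then the
vector is renormalized (so every feature's relative mean shifts — the
compositional artifact the compensated mode removes).  With compensation,
`floor(k/(1+FE))` flagged features go up by FE and the remaining flagged
ones are multiplied by `(a/b)(1−FE) + 1` (a, b = up/down flagged mass),
which conserves the flagged total exactly, leaving unflagged features
untouched by renormalization; degenerate draws (zero down-mass or a
non-positive multiplier) are redrawn from the same stream and logged.  The
rounding choices (up-count floor; half = ⌊k/2⌋) are this package's, as the
procedure's description leaves them open.  The sparsity effect adds
(down-regulated) or subtracts (up-regulated) a constant to the ZINB mixing
probability in group 2, clamped to [0, 1]; it is forced to 0 for NB
designs.

Counts are drawn per cell from NB(`lib_j·r_f^(group)`, phi) (Poisson when
phi = 0) with independent seeded streams for flag draws, library sizes and
counts, so changing one grid axis does not reshuffle the others; a dataset
is fully reproducible from (seed, replicate index).  Sharing the flag
stream across grid cells gives common random numbers for paired
power comparisons.

Power evaluation scores adjusted-p calls at alpha = 0.05 (TPR/FPR) and the
ranking by raw p (missing last) via the partial AUROC on FPR ∈ [0, 0.1]
(raw area, max 0.1, and the normalized variant raw/0.1), averaged over
replicates; failed replicates are dropped per method with a count.

## Rank aggregation

Per-criterion scores (KS ↓, |FPR − α| ↓, WMC ↑, TP−FP ↑, pAUROC ↑ by
default; directions and weights configurable) are ranked with mean ranks
for ties, averaged over the criteria available to each method (methods
without p values lack the type-I column and are flagged incomplete), and
normalized as `(avg_rank − 1)/(K − 1)` so 0 is uniformly best.  Wall-clock
time can be reported alongside but is excluded from the default ranking.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on synthetic data at desk
scale, chosen to keep each check's Monte-Carlo error well below its
tolerance: calibration uses 200 mock splits of a 41-sample null table
(~180 features after filtering); injection algebra uses 100 flag draws at
F = 250; the CAT expectation uses 1000 random ranking pairs at F = 100; the
power grid uses F = 200, 10% DA, fold effects {2, 5} × {10, 20, 40} samples
per group with 10 replicate datasets per cell for every built-in method.

## What the synthetic data do not show

The generators emulate depth, sparsity and composition regimes, not real
microbial ecology: no phylogenetic or co-occurrence structure, no
subject-level correlation, no batch/center effects (the metadata fields
exist for real data), a single common dispersion, and independent features
given the library size.  Passing calibration and power checks on these
tables therefore demonstrates correctness of the machinery and the expected
qualitative ordering of methods (matching-model advantage, liberal robust
dispersion, conservative compositional Monte-Carlo tests), not performance
guarantees on real studies.  Two further documented limitations: recovery
of template parameters from realized library totals is compositionally
distorted when a single taxon dominates the reads (see the simulator
tests), and with ~20 truly-DA features an adjusted-p TPR is granular at one
discovery, so weak-signal comparisons are evaluated as majorities over
replicate datasets rather than strict inequalities of averages.
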