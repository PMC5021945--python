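# Methods

This note documents the statistical models, the synthetic-cohort
generator, the numerical choices, and the limitations of `ffpesig`.

## Survival model and screening

Gene-level screening uses the univariate Cox proportional-hazards
model per gene, h(t|x) = h0(t)·exp(βx), with x the (log2) expression
of one gene. Endpoints are 5-year overall survival (OS) and
disease-free survival (DFS): any follow-up beyond 60 months is
administratively censored at 60 months before fitting. The 60-month
administrative-censoring mechanism is an interpretation — "five-year
outcomes" could also be realized by cohort selection — and is exposed
as `horizon_months`.

The partial likelihood uses the Efron approximation for tied event
times, the default of the reference survival ecosystem. β is maximized
by Newton–Raphson from β = 0 with step-halving whenever a step would
decrease the likelihood; convergence is |Δβ| < 1e-9 with at most 50
iterations. Monotone likelihood (risk perfectly ordered by the
covariate) is detected at |β| > 15; the estimate is clipped and
flagged, which leaves the score test untouched since it is evaluated
at β = 0. Zero-variance covariates yield a degenerate record (β = 0,
p = 1) rather than an error so that gene universes stay aligned across
platforms.

The p-value that drives all downstream thresholds is the **score test
at β = 0**, which for a binary covariate with distinct event times is
algebraically identical to the classical two-group log-rank chi-square
(asserted to 1e-8 in the tests); Wald and likelihood-ratio p-values
are computed and stored alongside. Multiplicity across genes is
handled by the Benjamini–Hochberg step-up, q(i) = min over j ≥ i of
p(j)·m/j, with "significant" meaning q < 0.05.

The two-group log-rank test uses the hypergeometric variance with the
(n−d)/(n−1) tie correction. At very small n the chi-square reference
for this statistic carries inherent finite-sample error (up to ~0.035
on the p scale at n = 20, measured against exact 10,000-permutation
references); the tests document and bound this rather than hide it.

Kaplan–Meier estimation is the standard product-limit estimator;
samples censored at an event time remain at risk for deaths at that
time.

## Preprocessing

**Count platform.** QC runs on raw counts, before any normalization.
A sample's detection threshold is mean + 3·sd of its own negative
controls (sd with denominator n−1; a single negative control has
sd 0). A sample fails when its average endogenous count is ≤ 1000
(closed inequality) or its missing rate — fraction of endogenous genes
at or below the threshold — is ≥ 0.20. "Average count" is computed
over endogenous genes only, because control counts are fixed by assay
design and would dilute the signal. Normalization is a three-step
control-driven procedure: (1) per-sample scaling by the cohort mean of
positive-control geometric means over the sample's own (lane
efficiency); (2) subtraction of the per-sample negative-control mean
with clamping at 0 (background); (3) scaling by housekeeping geometric
means (RNA content); then log2(x+1). The pseudocount of 1 keeps zeros
at zero, and the output is therefore non-negative. The full option
grid of nCounter normalization software (alternative summary
statistics per step) is intentionally not reproduced; each step here
is explicit and unit-tested.

**Array platform.** Intensities are assumed to be log-scale already,
so the convolution background-correction step of classical RMA is
omitted; quantile normalization and median polish are implemented
faithfully. Quantile normalization maps every column onto the vector
of row-rank means with stable (row-position) tie-breaking, which makes
it exactly idempotent and gives all columns the identical sorted
multiset. Median polish iterates row/column median sweeps (tolerance
1e-8 on the total absolute residual, max 20 iterations) and returns
overall + column effects. Probes mapping to multiple genes are
removed; when several probe sets remain for one gene, the one with the
largest interquartile range (midpoint-interpolation quantiles) is
kept, with exact ties broken by smallest probe id for determinism.

**Batch adjustment.** ComBat-style parametric empirical Bayes without
covariates: per-gene standardization by pooled mean/variance, per
gene×batch location (γ) and scale (δ²) estimates, normal prior on γ
and inverse-gamma prior on δ² fitted across genes by moments, solved
by the standard iterative update (relative change < 1e-4, max 100
iterations). With shrinkage off the estimates are used raw, which
removes a pure location-shift batch effect exactly. Zero-variance
genes are passed through unadjusted with a warning (clamping upstream
can create constant rows). Every batch must have ≥ 2 samples in either
mode, since the scale estimate needs a variance. The non-parametric
ComBat mode is out of scope. Negative values created by adjustment are
replaced by 0 in a separate explicit step.

## Concordance

Sample-wise correlations are Pearson r over the common genes of each
matched pair (Spearman reported alongside); gene-wise correlations are
computed across pairs. Constant vectors yield an explicit
undefined flag, not silent NaN propagation, and no variance filtering
is applied. The CI on a mean correlation is a percentile bootstrap
(1000 resamples, seeded); BCa was not used because a plain percentile
interval is the conventional report for this quantity. The one-sided
two-sample KS comparison of −log10 p distributions takes the signed
sup of the empirical CDF difference over pooled jump points in the
direction named by `alternative` and uses the asymptotic one-sided
p = exp(−2mnD²/(m+n)); the direction is a named parameter so reports
state which platform's CDF is claimed to lie above. The statistic is
invariant under common strictly monotone transforms, so the −log10
mapping affects interpretation, not the test.

## Signature evaluation

Published signatures arrive as gene lists with per-gene direction of
change in poor-outcome tumors. Evaluation:

1. *Direction filtering* (optional): keep gene g iff (direction up and
   fitted log HR > 0) or (direction down and fitted log HR < 0) in the
   evaluation cohort itself, on the endpoint set by `filter_endpoint`
   (default DFS; the choice of endpoint is genuinely open and exposed).
   Genes absent or degenerate are dropped and logged; genes without
   direction information are kept and flagged. Because the filter
   reuses the same cohort's hazard estimates it is optimistically
   biased — the unfiltered evaluation is always produced alongside.
2. *Risk score*: per-gene median-centering (subtract the across-sample
   median), sign-flip of "down" genes so a higher score always means
   higher predicted risk (`flip_down_genes`, default true; dividing by
   the median instead of subtracting was rejected because log2 values
   near 0 make ratios unstable), then the per-sample mean over
   signature genes.
3. *Median split*: scores above the cohort median are high-risk, below
   are low-risk; scores exactly at the median go low, then the tied
   samples with the largest sample ids move high until the group sizes
   differ by at most one. For even n with distinct scores this gives
   exactly n/2 per group.
4. *Evaluation*: KM curves per group and the two-group log-rank test
   per endpoint within the 60-month window.

## The synthetic-data generator

The generator replaces patient data and defines the conditions under
which every stage is validated.

**Latent layer.** z[g,s] = μ_g + γ[g,batch(s)] + σ·w[g,s] with
μ_g ~ N(8, 1.5) (log2 counts scale), per-gene batch offsets
γ ~ N(0, `batch_shift_sd`) (default 0.5 log2 units, a mild processing
effect), and biological variation σ = `noise_sd` (default 1.0 log2
units, typical for bulk tumor expression).

**Prognostic structure.** Signature genes in real cohorts are
co-expressed members of transcriptional programs, and a univariate
screen estimates each gene's *marginal* hazard association. The
generator therefore draws a per-sample latent risk factor u ~ N(0,1),
sets each prognostic gene's standardized expression to
w_g = d_g(√ρ·u + √(1−ρ)·ε_g) with module correlation
ρ = `module_corr` (default 0.5) and sign d_g, and lets the hazard act
on the factor, h(t|s) = λ0·exp((β/√ρ)·u_s), so each prognostic gene's
marginal log HR per sd of expression is d_g·β with
β = `log_hr_magnitude` (default 1). An additive model over independent
genes was considered and rejected: with k prognostic genes it dilutes
every marginal signal by 1/√k, so no univariate screen could recover a
50-gene signature regardless of implementation — an unrealistic and
untestable regime. A consequence of the factor design is that the
per-gene effects are exactly exchangeable given u; it does not model
multiple independent modules.

**Survival.** Event times are exponential, rate λ0·exp(η) with
λ0 = `baseline_hazard` (default 0.01/month; median survival ≈ 69
months, a plausible stage II–III scale). Censoring is independent
Uniform(0, u) with u solved (Brent) so the censored fraction at the
baseline hazard matches `censor_rate` (default 0.3); `censor_rate` = 1
draws censoring times before any event. OS and DFS share the linear
predictor but use independent draws — they are correlated only through
η, recurrence is not modeled explicitly. Exponential baseline +
uniform censoring keep closed-form checks (KM vs exp(−λt)) available.

**Count rendering.** Endogenous counts are negative binomial with mean
`count_scale`·2^z·efficiency and variance m + φm² (φ =
`count_dispersion`, default 0.1; φ→0 recovers Poisson). Per-sample
efficiency is lognormal(0, 0.15); a fraction `frac_low_quality`
(default 0.2) of samples gets efficiency 0.02, low enough to fail both
QC rules — emulating degraded FFPE blocks. Positive controls follow a
fixed six-point spike-in ladder shared across samples and scaled by
efficiency; negative controls have constant mean `neg_control_mean`
(default 15); the seven housekeeping genes (matching the common
codeset design) come from low-variance latent rows.

**Array rendering.** Each gene emits `n_probes_per_gene` probe rows
z + affinity + noise with affinity ~ N(0, `probe_affinity_sd`) and
probe j's noise sd scaled by (1+j), so sibling probe sets differ in
variability and the largest-IQR rule has something to choose between;
`n_multigene_probes` extra probes map to two genes each to exercise
the drop rule.

**What the generator does not emulate**, and hence what passing tests
do not show about real data: FFPE degradation chemistry (fragment-length
effects, storage-time trends), probe-sequence biases, multiple
co-expression modules, non-proportional hazards, informative
censoring, and clinical covariates (stage, MSI). Cross-platform
correlations in the synthetic cohorts are higher than typical archival
FFPE studies because measurement noise here is mild and shared latent
expression is exact.

**Randomness.** One root seed; named substreams are spawned in the
fixed order (latent, survival, counts, array, signature), so all
renders are bit-reproducible and independent of call order.

## Problem sizes used in the test suite

Simulation-based tests use cohorts chosen to make their target effects
decisively measurable while keeping the default suite quick: global-null
calibration uses 100 replicates of 500 genes × 100 samples;
parameter recovery uses 516 genes × 300 samples with 50 prognostic
genes; signature power and type-I use 100 replicates at n = 300;
bootstrap coverage uses 500 simulations of n = 42; the permutation
oracle uses 10,000 permutations at n = 20 and n = 200. The pipeline
demo mirrors the paired-study geometry (516 genes, 42 matched pairs).

## Known limitations

* The direction filter's reuse of the evaluation cohort's hazards is
  circular by construction; treat filtered log-rank p-values as
  descriptive, and compare with the unfiltered variant.
* The score/Wald/LRT trio is computed per gene, but only the score
  p-value feeds multiplicity adjustment and thresholds.
* The KS p-value is asymptotic and one-sided; at very small gene
  counts an exact permutation version would be preferable.
* Gene symbols are the cross-platform join key, case-sensitive, with
  no alias resolution — annotation-version drift must be resolved
  upstream in the probe map.
* The empirical-Bayes batch model assumes exchangeable gene effects
  within batch and no outcome-batch confounding; batches must be known
  labels (no surrogate-variable estimation).
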