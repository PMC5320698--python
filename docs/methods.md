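# Methods

## Scope and model

`wmhtrial` sizes two-arm randomised trials whose outcome is white-matter-
hyperintensity (WMH) burden one or two years after baseline, measured either
as a volume in ml or as the ordinal Fazekas score (periventricular + deep,
0–6). Three design families are covered: normal-theory comparison of
follow-up volumes with ANCOVA variance deflation, Whitehead's
proportional-odds formula for ordered categorical outcomes with a stratified
covariate multiplier, and a Wilcoxon rank-sum design via the tie-corrected
Noether approximation. A synthetic cohort generator reproduces the
statistical structure of a mild-ischaemic-stroke cohort so that the
observational analysis stage and all design formulas can be tested end to
end without access to patient data, and a Monte-Carlo engine verifies every
closed-form size by simulating complete trials.

## Continuous designs

The per-group completer requirement is
`ceil(2 (z_{1-α/2}+z_{1-β})² σ² (1-R²) / (δ·years)²)`. Normal (z) quantiles
are the default because published sample sizes in this setting are
z-based; a Student-t fixed-point correction is available via `use_t=True`.
`apply_r2_adjustment` implements the deflation as a separate step
(`ceil(n·(1-R²))`); the two routes agree within ±1 by construction and the
suite asserts it. Rounding is always ceil at the per-group stage, then
doubled; this single rule reproduces every dropout-inflated recruitment
total in the reference design menu. Duration scaling multiplies the
detectable difference by the follow-up years while holding the outcome SD
constant — the reference calculations assume the same per-year progression
and are silent on SD growth, so the package makes the constant-SD choice
explicit rather than modelling variance inflation over time.

Attrition: completers per group are divided by the retention
`(1-rate)^years` and rounded up before doubling (20%/year compounds to 36%
over two years).

## Whitehead's formula and the anchored path

The per-group size is
`ceil(6 (z_{1-α/2}+z_{1-β})² / ((log OR)² (1-Σ p̄³)))`, where `p̄_k`
averages the anticipated control and treatment probabilities of category k
and the treatment distribution shifts the control cumulative log-odds by
`log OR` (OR > 1 moves mass toward lower categories). The constant 6 (12 on
the total) is Whitehead's; two internal consistency checks pin it down
independently: the Monte-Carlo engine attains the design power at the
returned n (and half of it at half the constant), and the Noether rank
formula below reduces to it in the small-effect limit.

Published ordinal sizes often omit the category distribution that produced
them. `backsolve_denominator` inverts the formula to recover the implied
distribution term; for the reference menu's OR-1.2 row the back-solved term
(0.9451) essentially equals the term of the published baseline Fazekas
marginals, confirming the anchor's interpretation. When a sweep is anchored
at a published integer size, downstream sizes are rounded to **nearest**
rather than up: the anchor itself was rounded, so its ±1 slack would
otherwise surface as spurious +1s at integer boundaries (ceil would turn the
OR-1.16 value 2262.001 into 2263). The explicit-distribution path keeps
ceil.

The covariate multiplier for a stratified ordinal analysis is the ratio of
the unstratified distribution term to the prevalence-weighted mean of the
within-stratum terms, applied as `ceil(n_base · multiplier)`. A stratum
concentrated in one category carries no rank information and drives the
multiplier toward infinity; this is reported with a warning rather than
silently truncated.

## Rank-sum designs

`θ = P(T > C) + ½P(T = C)` is computed exactly by enumeration over the two
category distributions, and the per-group size is
`ceil((z_{1-α/2}+z_{1-β})² (1-Σ t̄³) / (6 (θ-½)²))` with `t̄` the
combined-sample category probabilities. This is an approximation (Noether's
formula with a tie correction); the Monte-Carlo engine is the arbiter, and
at the sizes it returns the simulated rank-sum power sits within sampling
error of the target. θ = ½ (identical distributions) is an error, not a
size of infinity.

## Monte-Carlo power engine

Continuous trials draw marginally normal outcomes; the optional baseline
covariate is realised as a standard normal with the stated squared
correlation to the outcome, so the same simulated trials can be analysed
unadjusted (two-sample z or t) and adjusted (ANCOVA t-test on the treatment
coefficient, computed by Frisch–Waugh partialling, vectorised across
replicates). Ordinal trials draw per-arm multinomial category counts; the
proportional-odds analysis is the Mann–Whitney/Wilcoxon score z computed in
closed form from the counts with the usual tie correction and no continuity
correction, which makes a 2000-replicate run a single array computation.
This statistic is checked against `scipy.stats.mannwhitneyu` in the suite.
A full per-replicate proportional-odds ML fit is not provided; the score
test is the asymptotically equivalent standard choice, and at the sample
sizes these designs produce the difference is negligible. Heterogeneous
per-category cumulative odds ratios construct non-proportional-odds
scenarios; a combination whose cumulative probabilities would be
non-monotone is rejected as an invalid scenario.

Defaults: 2000 replicates (binomial SE ≈ 1.1 percentage points near 80%
power), two-sided α = 0.05. Every estimate carries a Wilson 95% interval,
its replicate count and its seed; identical plans give bitwise-identical
estimates.

## Synthetic cohort generator

The generator emulates, at the configured n, the published marginal
structure of a 264-patient mild-stroke cohort followed for one year:

* **Baseline WMH volume**: lognormal, moment-matched to mean 22.0 / SD
  24.8 ml (log-mean 2.681, log-SD 0.906). Only mean±SD and nonnegativity
  are published; lognormal is the natural right-skewed choice for lesion
  volumes.
* **Baseline Fazekas**: ordered logit in volume with slope log(1.21) per
  ml. The six cutpoints are back-solved so the *marginal* category
  frequencies match the observed proportions (4.2, 9.0, 36.8, 12.6, 15.3,
  9.0, 13.2%, renormalised); each cumulative probability is a monotone
  function of its own cutpoint, so calibration is six independent 1-D root
  finds against a Gauss–Hermite integral over the volume distribution
  (tolerance 1e-10).
* **Covariates**: age N(65.3, 11.3²); MAP and pulse pressure bivariate
  normal (102.8 ± 15.4, 63 ± 20.7) with default correlation 0.3 (no
  published covariance; 0.3 is a typical clinic value), pairs redrawn while
  PP ≤ 0 so systolic always exceeds diastolic (≈0.1% of draws); five binary
  risk factors as independent Bernoullis at the published prevalences. The
  hypertension flag is drawn at its printed prevalence rather than derived
  from the generated pressures — the printed prevalence is the calibration
  anchor. All remaining covariates are mutually independent; no covariance
  structure is published.
* **Follow-up volume**: linear in the ten predictors with the published
  adjusted coefficients; Gaussian noise is resampled until the draw is
  nonnegative (no point mass at zero). The intercept and residual SD are
  solved at calibration time on a large fixed-seed covariate draw: the
  residual SD from Var(linear predictor) and the target R² = 0.90, the
  intercept by root-finding on the truncation-corrected expected follow-up
  so the mean 1-year change is 1.27 ml. Neither number is hard-coded.
* **Follow-up Fazekas**: the same ordered-logit map applied to the
  follow-up volume, so scores can regress, mirroring the observed volume
  decreases.
* **Informative dropout**: logistic in age and baseline Fazekas. The
  Fazekas coefficient defaults to 0.15 per point (a modest effect matching
  the borderline observed association); the intercept and age coefficient
  are solved jointly for a 28% overall rate and a 5.7-year age gap between
  completers and non-completers. Reasons are multinomial at the observed
  frequencies (33:24:5:6:6), and dropout blanks exactly the follow-up
  fields.

Everything is driven by one integer seed through per-stage
`numpy.random.Generator` streams; identical config + seed is bitwise
reproducible.

What the generator does **not** emulate: measurement error of the
volumetric pipeline or of visual rating, scanner drift and between-scanner
variation, more than two timepoints, non-random missingness beyond the
age/Fazekas logistic, and any covariate interactions. Passing tests
therefore show that the analysis stage recovers the generative model and
that the design formulas are internally consistent — not that the published
cohort's unpublished joint structure is reproduced.

## Analysis stage

OLS (statsmodels) on complete cases for the univariate and multivariable
progression models, with Wald 95% CIs; rank-deficient designs raise an
error naming the collinear columns. VIFs are computed from first principles
as `1/(1-R²_j)`, reporting infinity with a warning under perfect
collinearity. The per-ml odds ratio comes from a proportional-odds model
(statsmodels `OrderedModel`, logit link, BFGS). Completers-vs-dropouts
comparisons use Welch t tests by default (the pooled-variance test is a
flag; the reference analysis does not say which was used) and chi-square
tests without continuity correction (also a flag), with the sign convention
completers minus non-completers.

## Problem sizes used in the suite

The suite's cohort-level checks run at n = 100,000 (shared session
fixture), where calibration targets are resolvable to: volume moments
within 2%, Fazekas marginals within 2 points, mean progression ±0.12 ml,
follow-up SD within 5%, R² ±0.02, OR ±0.02, dropout ±1.5 points, age gap
±0.5 years. Power simulations use 1000–2000 replicates with 3-binomial-SE
tolerances. The pipeline demonstration runs at n = 2000 with 200–500
replicates, enough for the fitted quantities to sit within the tolerances
above while the whole suite completes in well under a minute.

## Known limitations

* The exact unrounded SD, R² and category distributions behind some
  published sizes are unrecoverable; the engines bracket those cells within
  ~2–3% (e.g. 8523 vs 8508 per group from the rounded SD) and reproduce
  exactly the arithmetic that is exactly reproducible (dropout chains,
  anchored OR scaling, multipliers applied to rounded bases).
* The stratified multiplier reproduces the published hypertension cell
  (1.00057 → 1500); the published age and Fazekas-stratified cells are 1–2
  patients away from any rounding rule applied to the printed inputs and
  are treated as rounding artefacts of the source, not targets; the
  Fazekas multiplier (5.04) and rank-sum size (87,216) depend on
  unpublished cross-tabulated/follow-up distributions and are reproduced
  only through their printed per-group sizes.
* Designs are single-look; no sequential or adaptive features, no cluster
  randomisation, no unequal allocation, no multiple imputation for
  informative missingness.
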