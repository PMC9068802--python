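# Methods

## Model

Let x be end-of-primary educational performance (CITO-like score,
mean-centered against the analysis sample) and y secondary-school
attainment on the 0–4 track-level scale, treated as continuous.  For
each twin, unit-variance latent factors A, C, E act on both phenotypes
through a Cholesky ordering of x before y:

```
x = μ_x + β'cov + a_xx·A_x + c_xx·C_x + e_xx·E_x
y = μ_y + β'cov + ã_yx·A_x + c̃_yx·C_x + ẽ_yx·E_x      (common part)
          + ã_yy·A_y + c̃_yy·C_y + ẽ_yy·E_y             (unique part)
```

A factors correlate r across co-twins (1 for MZ, 0.5 for DZ), C factors
are fully shared within a pair, E factors are twin-specific.  Each
attainment path may be moderated linearly by the twin's own centered
performance X: `ã_yx = a_yx + a′_yx·X`, and so on for the six y paths;
performance paths carry no moderation.  X is handled as a *definition
variable*: the observed value enters the model-implied moments, so every
pair has its own 4×4 covariance of (x1, y1, x2, y2).  In pairs
discordant for tracking timing, each twin's own status selects its
parameter set, and cross-twin covariances multiply the two twins'
effective paths — the standard definition-variable treatment, which the
source design leaves implicit.

Raw variance components are squares of (moderated) paths; standardized
components divide by the conditional total `V_y|X`.  Because components
are squares, path signs are partially a gauge freedom: loadings of one
latent factor may be negated together without changing the likelihood.
A factors and C factors enter cross-twin products that mix statuses in
discordant pairs, so they admit only a *global* (all-status) flip; E
factors are twin-specific and can be flipped per status.  At
convergence, signs are canonicalized so `a_xx, c_xx, e_xx, a_yy, e_yy ≥ 0`
(anchored at the first status for the global factors); `c_yy` keeps its
estimated sign, as the unique shared-environment path is the one path
conventionally reported with a sign.

## Model specifications and estimation

Three nested specifications:

| model | structure | free parameters (3 statuses) |
|---|---|---|
| 1a | one parameter set for all tracking statuses | 11 + 4 = 15 |
| 1b | full set per status (immediate, delayed, unknown) | 33 + 4 = 37 |
| 2  | 1b + six moderation slopes per status | 37 + 18 = 55 |

A per-status set is 2 intercepts + 3 performance paths + 6 attainment
paths.  The four covariate slopes (sex, birth year, on each phenotype)
are shared across all groups in every model.  Tracking-status-unknown
twins form a genuine third parameter group in models 1b/2 and share the
common set in 1a.  Freeing 1a → 1b therefore adds 22 parameters and
1b → 2 adds 18, which fixes the likelihood-ratio degrees of freedom.
An optional main effect of the moderator on the attainment mean
(`b_mod_y`, per status) is exposed but off by default, and every fit
records whether it was used.

Estimation is full-information maximum likelihood: each pair contributes
`k·ln 2π + ln|Σ_obs| + (z−μ_obs)ᵀ Σ_obs⁻¹ (z−μ_obs)` for its observed
subvector.  A twin with a missing moderator contributes no terms at all
(its performance and attainment are dropped) while the co-twin is
retained — the record-level exclusion rule of the design.  Pairs are
grouped by missingness pattern and the likelihood is evaluated in
batched linear algebra; the analytic gradient chains the Gaussian score
`W = Σ⁻¹ − Σ⁻¹zzᵀΣ⁻¹` through the bilinear path structure and the
parameter-tying map, and is verified against finite differences in the
test suite.

The optimizer is L-BFGS-B on the raw paths (no positivity bounds — a
negative `c_yy` is a legitimate estimate) from a Falconer-style
method-of-moments start, with jittered restarts (default 5; the
pipeline uses fewer with warm starts from the previous model, which the
start-invariance test justifies).  Convergence targets a projected
gradient below 1e−5 with a tight relative-f tolerance.  Non-positive-
definite implied covariances are penalized, never fatal.  Standard
errors come from `2·H⁻¹`, with H the central finite-difference Hessian
(step `1e−4·max(1,|θ|)`, built from the analytic gradient).  Near-zero
curvature directions — e.g. a path estimated at zero, whose sign is
locally unidentified — are clipped in the eigendecomposition so they
yield large variances rather than corrupting every SE.  Delta-method
intervals for derived quantities (standardized shares, variance sums)
use a numerical gradient of the transform against this covariance;
profile-likelihood intervals are out of scope.

Two AIC conventions are reported and labeled: the standard `−2LL + 2k`
and the Mx-style `−2LL − 2(n_obs − k)`, where `n_obs` counts observed
data points; published tables in this literature often use the latter.

## Synthetic data generator

`simulate_pairs` draws from exactly the model above: correlated A
factors via `√r·A_shared + √(1−r)·A_unique` (so MZ and DZ differ only in
r), shared C, twin-specific E, and attainment built from paths evaluated
at the twin's own realized centered performance.  Tracking status is
drawn per twin from a pattern model — a pair-level status-unknown
probability, zygosity-specific discordance rates (defaults 4% MZ,
13% DZ), and a marginal delayed share (default 26%) — so pair
concordance emerges rather than being imposed.  Item missingness blanks
fields independently at configurable rates.  The default configuration
(`GenerativeConfig.default()`) encodes the study conditions: the
immediate-tracking group with a large shared-environment influence, the
delayed group with almost none and a smaller performance variance, a
status-unknown group at the pooled values, zero moderation slopes,
covariate effects of plausible magnitude (males ~0.6 CITO points and
~0.06 track levels higher; a small birth-year trend), ~33% of pairs with
unknown status, and 35% attainment missingness; 3000 pairs (55% MZ) is
the default demo size and ~4941 pairs the reproduction-script size.

What the generator does *not* emulate: gene–environment correlation,
assortative mating, non-additive genetic effects, floor/ceiling effects
of the 0–4 track scale (simulated attainment is genuinely continuous
and may fall outside [0, 4] — clipping would bias recovery tests), or a
performance-dependent tracking assignment inside the main generator.
The last exists as a separate logistic op
(`assign_tracking_by_performance`, P(delayed|X) = expit(α + βX)) for
selection descriptives, because the source design reports the selection
pattern but no selection model; with it, status and parameters are no
longer jointly consistent with the fitted multigroup model, so recovery
tests use the pattern-model generator.  Passing tests therefore show
that the estimator recovers its own generative process at realistic
sizes and noise levels — not that real register data satisfy the twin
model's assumptions (equal environments, additivity, no assortment).

## Descriptives and checks

* **Twin correlations** are double-entered (each pair contributes both
  orderings) — deterministic, and standard in this field.
* **Crosstabs** of twin-level factors (parental education, CITO bins
  with the conventional cut points 500–518 … 545–550) against tracking
  timing use a Pearson chi-square with a Rao–Scott second-order
  correction for the dependence of twins within a pair: a linearization
  covariance with cluster = pair and equal weights, generalized design
  effects `δ` on the independence-contrast space, corrected statistic
  `X²/(δ̄(1+a²))`, and a Satterthwaite F with fractional dfs
  `d/(1+a²)` and `(M−1)·d/(1+a²)`.  Finite-sample factors are chosen so
  singleton clusters reproduce the Pearson statistic exactly, and the
  statistic is invariant under duplicating members within clusters
  (perfect dependence).  Counts are twin-level; the pair is only the
  clustering unit.
* **Homogeneity checks** fit per-zygosity bivariate normals to
  (twin1, twin2) and constrain step by step: variances equal across
  birth order, then zygosity; means equal across birth order, then
  zygosity; then no sex shift in means.  Twin correlations stay
  zygosity-specific throughout (they genuinely differ under the model).
  Each step is reported as an LRT against the previous model.

## Numerical and design choices

* Attainment recoding: 0 = VMBO-b, 1 = VMBO-k, 2 = VMBO-g/t, 3 = HAVO,
  4 = VWO/Gymnasium; survey-era combined categories score 1.5
  ("VMBO", 2004–2008 surveys) and 0.5 ("VMBO", 2009–2014); multiple
  reported levels average.  Tracking timing: two or more track levels in
  the child's class ⇒ delayed; mother's report has priority over the
  father's.
* Pairs with exactly one missing tracking status: each twin keeps its
  own status for modeling (the missing twin uses the unknown-status
  set); the pair-level descriptive label is "tracking-missing".  The
  source design does not state its rule; this one discards no
  information.
* Centering constants (performance mean, birth-year mean) are computed
  from the loaded sample and stored on the table, so fits are
  reproducible; generation-scale intercepts are translated onto the
  centered analysis scale by `analysis_truth` for recovery comparisons.
* Problem sizes in the test suite are chosen for statistical
  meaningfulness at interactive runtimes: recovery uses 3000 pairs
  (immediate/delayed groups, where delta-method share SEs are ≈0.04, so
  a ±0.05 recovery band is informative), and null calibration uses 200
  replicates of 500 pairs, where the observed rejection rate at
  α = 0.05 is ≈0.045.

## Known limitations

Ordinal attainment is treated as continuous (equal category spacing);
no liability-threshold, dominance (ADE), or sex-limitation models; no
profile-likelihood or bootstrap intervals; the selection model for
tracking timing is a stand-in logistic; standard errors assume a
correctly specified likelihood (no sandwich correction).
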