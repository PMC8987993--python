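# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and what the package's tests do and do not
establish.

## Synthetic cohorts

The generator is the package's ground-truth harness. Each regional
feature f follows an independent trajectory

    mu_f(age, sex) = b0 + b1 (age − 50) + b2 (age − 50)^2 + bs · sex,
    value = mu_f + Normal(0, sigma_f^2),

with sex coded female = 0, male = 1. Default parameters are drawn once
from a fixed seed and are chosen to be biologically plausible rather
than calibrated to any dataset (no public reference tables exist for
these feature panels): volumes 3–30 mL declining 0.15–0.4 %/year,
thickness 2.0–3.2 mm declining 2–6 µm/year, GFA 0.30–0.55 declining
(0.5–1.5)·10⁻³/year, MD 0.65–0.95 (units 10⁻³ mm²/s) rising
(0.8–2)·10⁻³/year; b2 defaults to 0. Residual SDs are expressed as an
*age-equivalent noise* of 6–12 years per feature
(`sigma_f = |b1| · U(6, 12)`): a single feature dates a brain only to
within a decade, while the full 124- or 90-feature panel does so to
about a year — the regime in which brain-age modeling is meaningful.
GFA draws are clipped to (0, 1) with margins wide enough that the clip
is statistically irrelevant.

The normative population samples ages from a truncated normal
(mean 36.9, SD 19.1, range 14–92) and sex with 47% male — the
composition of a typical lifespan training cohort. Clinical groups
default to ages 50–85 (mean 66, SD 7).

A clinical group applies an **effective-age shift**: every feature is
evaluated at `age + delta_i`, with `delta_i = pad_shift + jitter`
(jitter SD 2 years by default). This makes "true PAD" well defined and
recoverable. `pad_shift_features` optionally restricts the shift to a
named subset, creating ground truth for attribution tests; and
`deviant_features` adds focal shifts in units of `sigma_f` for
normative-recovery tests. Clinical scores are linear in the realized
`delta_i` plus noise, with default couplings sized to give a true
correlation of 0.4.

What the generator does **not** emulate: inter-regional covariance
(residuals are independent), site/scanner effects, non-Gaussian noise,
and any real disease topography. Passing recovery tests therefore shows
the *estimators* are correct and calibrated under the stated model, not
that the pipeline's empirical findings transfer to real cohorts.

## Brain-age model

A cascade-forward network: hidden layer k receives the original
(standardized) inputs concatenated with all previous layers' outputs;
the single linear output unit sees the inputs plus every hidden layer.
Twelve hidden layers of width 16 with tanh activations by default. The
input-to-output skip connection means the architecture contains the
linear model exactly, which the capacity test exploits (noiseless linear
data must be fitted to MAE < 0.5 years).

Training minimizes MSE (plus L2 of 1e−3 on weights, in squared
standardized-target units) by full-batch L-BFGS-B with analytic
gradients, at most 500 iterations. Inputs are standardized per feature
and the age target is standardized internally (predictions are returned
in years); the linear read-out is warm-started by a ridge solve over
[inputs, initial hidden activations], which removes the slow "find the
linear part" phase of the optimization. A seeded 10% validation split
provides early stopping: the parameters with the best validation MSE
along the optimization path are kept. Everything is deterministic given
`random_state`. Cross-validation uses a seeded uniform permutation into
k folds whose sizes differ by at most one; pooled r/MAE are computed on
the concatenated out-of-fold predictions.

## PAD and bias correction

`PAD = predicted − chronological` age. The linear correction regresses
PAD on age in a reference sample by OLS and subtracts the fitted trend;
on the reference itself the corrected PAD is orthogonal to age to
machine precision. The pipeline default fits the correction on the
healthy-control group of the application cohort (configurable to a
training-set fit). Note the statistical caveat: the correction inherits
the sampling error of the reference slope (SE ≈ σ_PAD/(√n · SD(age))),
so a small or age-restricted reference leaves a residual slope of that
order on independent data; the slope-recovery check accordingly uses a
wide-age reference of n = 500.

## Normative models

One GP per feature with inputs (age standardized on the reference, sex
as 0/1). The model is semi-parametric: an unpenalized OLS basis
[1, age, sex] fitted on the full reference carries the dominant linear
trend, and the GP — squared-exponential kernel with ARD length scales
plus white noise — models only the residual structure. This avoids the
shrinkage a purely kernel-based fit applies to the linear trend, which
otherwise tilts held-out Z-scores. The RBF length scales are bounded
below at 0.75 scaled units (≈ 15 years): aging trajectories are smooth
over decades, and shorter scales only chase noise.

For cubic-cost control each GP is fitted on a seeded subsample (default
250) of the reference, with 2 restarts of the marginal-likelihood
optimization. Two full-sample recalibrations follow: (1) the linear
basis is refitted against the GP's full-sample residuals, removing the
small intercept/tilt a subsampled GP can re-introduce through its
near-constant kernel components; (2) the predictive SD is rescaled so
the full-sample standardized residuals have unit RMS, removing the
subsample's chi-square fluctuation (≈ √(2/m)) from the noise estimate.
Both corrections use only reference data.

The predictive SD includes the white-noise term (a "new observation"
norm), so held-out healthy Z-scores are approximately standard normal.
The per-feature calibration bounds (mean within ±0.1, SD within
[0.9, 1.1], |corr(Z, age)| < 0.1) are checked with a reference of
n = 2000 and a held-out sample of n = 2000: the per-feature mean error
scales as σ(1/√n_ref + 1/√n_hold), and at n = 500 the worst of 124
features would breach ±0.1 from sampling noise alone, which would test
the sample size rather than the estimator. Queries more than 5 years
outside the training age range trigger an extrapolation warning.
Degenerate (zero-variance) features are flagged and scored Z = 0 at
their constant.

## Robust effect size (MM-estimate)

The Z-vs-PAD association is scored on median/MAD-standardized variables
by an MM regression: an S-estimate of (slope, intercept) minimizing a
Tukey-bisquare M-scale (c = 1.547, breakdown 0.5) over seeded two-point
elemental candidates refined by IRLS, followed by an M-step with the
redescending bisquare at c = 3.44 (85% efficiency at the normal) with
the S-scale held fixed. The slope is the effect size, clipped to
[−1, 1]; it is carried signed, ranking uses |ES|. Whether the original
analysis used the slope, a robust correlation, or a robust-R² derivative
is not specified anywhere we could check; the standardized-slope
convention is this package's documented choice (on standardized
variables it coincides with a correlation-like quantity). Zero-MAD
inputs are flagged degenerate rather than scored.

ΔES between two groups is the signed difference of per-feature effect
sizes; |ΔES| > 0.3 (a medium effect-size difference, configurable)
flags a feature. Regional aggregation reports
`100 · Σ|ES| in region group / Σ|ES| overall` within each feature type.

## Statistics

The ANCOVA group test comes from nested OLS models (full: intercept +
group dummies + covariates; reduced: covariates only), F with
df = (g−1, n−g−k). Post-hoc tests are the analogous two-group ANCOVAs,
BH-adjusted across the three pairs (the post-hoc procedure is a design
choice; contrasts within the full model are the main alternative).
Partial correlation residualizes both variables on [1, covariates] and
correlates the residuals, with p from t on n−2−k df. Two correlations
are compared by Fisher r-to-z with SE = √(1/(n₁−3) + 1/(n₂−3)) — this
choice reproduces the published between-group p-values (0.081, 0.212)
from the published (ρ, n) pairs. The outlier-exclusion re-analysis masks
the k smallest values per group (stable first-occurrence tie-break) and
reruns the ANCOVA.

## Problem sizes and determinism

Default study sizes: training/reference n = 500 (ages 14–92), clinical
groups n ≈ 20–200 depending on the check, normative calibration
n = 2000/2000 as justified above. These sizes make every recovery
target statistically decidable while keeping the full suite and the
acceptance script at a few minutes on one CPU. Every stochastic stage
(cohort draws, weight initialization, fold assignment, GP subsampling
and restarts, S-stage candidate sampling) takes an explicit seed, and
identical configs reproduce byte-identical outputs.

## Known limitations

- The cascade network's width/activation and training schedule are
  package defaults; the architecture family, loss, fold count and the
  12-layer depth are fixed, but no claim is made that these defaults
  match any particular published model's hyperparameters.
- GP normative models assume homoscedastic noise per feature;
  heteroscedastic aging (variance growing with age) would miscalibrate
  the tails.
- The MM effect size is univariate per feature; correlated features are
  scored marginally.
- Independent-residual synthetic data understate the multiple-testing
  burden real correlated panels produce.
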