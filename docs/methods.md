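# Methods

## Model chain

The quantity modelled is the free-sulfhydryl (SH) content of stored raw
ground pork, expressed as percent of the day-0 value, so SH(0) = 100 by
construction. Three layers build on each other:

**Primary (within one temperature).** SH is assumed to decay at a rate that
does not depend on the current SH level (zero-order kinetics):
SH(t) = SH₀ − k·t. `fit_zero_order` solves the closed-form normal equations;
k is reported as the negated slope so a decaying series has k > 0. By default
the intercept is free — the fitted SH₀ absorbs early-time curvature — and an
option pins SH₀ = 100, matching the normalization anchor. Replicates are
averaged per time point before fitting (for a balanced design this yields the
same slope as fitting every replicate point; both paths are available).

**Secondary (across temperatures).** The per-temperature rates k(T) are fitted
with two alternatives:

* *Arrhenius* k(T) = k₀·exp(−Eₐ/(R·T_K)), with R = 8.314 J mol⁻¹ K⁻¹ and Eₐ
  stored in kJ/mol. In a complex food matrix Eₐ is an empirical temperature-
  sensitivity index, not a reaction barrier. The default estimator is the
  linearized regression of ln k on 1/T (closed form, deterministic); a
  Levenberg–Marquardt fit of the exponential form (via
  `scipy.optimize.least_squares`, method `lm`, tolerances 1e-12, initialized
  from the linearized solution, parametrized in ln k₀ for conditioning) is
  provided because the two estimators weight errors differently on noisy
  rates. On noiseless rates they agree to ≤ 1e-6 relative — a property the
  test suite enforces.
* *Log-logistic* k(T) = m′·softplus(c·(T − T_c)) with m′ pinned at 1,
  evaluated in °C. softplus(x) = ln(1 + exp(x)) is computed as
  `logaddexp(0, x)` and is finite for |x| up to at least 10⁴. The fit runs
  Levenberg–Marquardt over (ln c, T_c) — optimizing ln c keeps the slope
  positive — initialized from the straight line through the two
  highest-temperature rates (deep in the softplus's linear regime).
  Non-monotone rate sequences are fitted anyway and flagged in the model's
  `warning` field.

**Combined predictor.** SH(t, T) = SH₀ − k(T)·t (`predict_sh`), exact at
t = 0, never clamped below zero (a warning is emitted instead), with a second
warning when T lies outside the fitted 4–20 °C range.

## Temperature conventions

Datasets store °C; Kelvin appears only inside Arrhenius evaluations, with
K = °C + 273 to match the published rate-constant grid (4 °C ↔ 277 K). The
shipped parameter table records T_c magnitudes as printed together with a
`tc_sign` flag. The package's internal convention requires the rate to
increase with temperature, which places T_c below the fitted range: for 11
treatments the internal T_c is the negative of the printed magnitude
(`negated`) — this choice reproduces the published 12 °C predictions — for
oregano the printed sign already does (`as_printed`), and for rosemary and
cardamom neither sign reproduces the published predictions
(`unverifiable`; they default to `negated` and are excluded from
reproduction tests). Two further cells in the published prediction table
(clove and onion at day 6) deviate from their own printed parameters by 0.05
and 0.10 SH units; the corresponding tests document and expose those
deviations rather than hide them.

## Validation metrics

All metrics come from residuals (observed − predicted): R² = 1 − SSE/SST with
SST about the pooled observed mean; adjusted R² with p model parameters;
RMSE = √(SSE/n); CV% = 100·RMSE/mean(observed). External validation evaluates
per-treatment predictors on a temperature withheld from fitting (12 °C by
default) and pools residuals across treatments into one report per model
family, with per-treatment sub-reports. Day-0 rows are included by default
(they are genuine observations even if anchored); a flag excludes them.
Published pooled RMSE/CV values for the holdout table are not recoverable
from the printed treatment means — they evidently pool replicate-level
residuals — so the package treats only the printed columns themselves as
reproducible ground truth.

## Treatment ranking (MLR)

`SH = β₀ + β_t·t + β_T·T + Σₑ βₑ·I(e)` over all records at all temperatures
(including the holdout — the ranking question is about treatments, not
prediction; a flag restricts to the training temperatures). The untreated
control is the uncoded reference, so each βₑ is the extract's mean SH
difference from the control; larger βₑ means better antioxidant protection.
Temperature enters in °C. The fit is ordinary least squares (statsmodels)
after an explicit rank check that names collinear columns; standard errors
use df = n − p and p-values are two-sided t-tests, uncorrected by default
(a Bonferroni option exists). Ties in the ranking are broken alphabetically.

## MLP ensemble

Inputs are 16-dimensional: a 14-way treatment one-hot block plus time and
temperature min-max scaled to the ranges of the learning split; the response
is min-max scaled to [0, 1] on the learning split and inverse-transformed for
prediction. Each of the 20 candidates draws a hidden size uniformly from
4–10, a hidden activation from {tanh, exponential} and an output activation
from {identity, logistic, tanh, exponential}, initializes weights
N(0, 1/√16), and minimizes the sum-of-squares error with BFGS
(`scipy.optimize.minimize`, analytic gradient, ≤ 200 iterations). The
exponential unit's pre-activation is capped at 50 to keep the loss finite;
candidates that still go non-finite are discarded with a logged warning. The
5 candidates with the lowest validation-split SOS are retained; prediction is
their unweighted mean. Per-split "performance" is reported as the
observed–predicted Pearson correlation, the regression analogue of a
percent-correct score and the quantity in the 0.95–0.99 range that such
protocols report. Everything — split, architectures, initializations — comes
from one seeded generator, so training is bit-reproducible. The network is
implemented in-package (forward pass + gradient) because no installed library
offers this activation envelope; a scikit-learn MLP serves as an independent
cross-check in the tests.

## Synthetic data

The kinetic generator emulates the study design: 14 treatments; 4, 8, 12, 16,
20 °C; sampling days (0,1,2,3,4,6,8,11) at 4 °C, (0,1,2,3,4,6) at 8 and
12 °C, (0,1,2,3,4,5) at 16 and 20 °C — day grids bounded by the 11/7/7/5/5-day
storage durations, with the 8–12 °C grid matching the published holdout
grid; 3 replicates. SH = 100 − k(T)·t + ε with per-treatment Arrhenius
ground-truth rates defaulting to the published parameter table and
ε ~ N(0, σ²) additive and homoscedastic on the percent scale. σ defaults to
2 SH-percent — the replicate spread is not published, and 2 % is consistent
with the magnitude of the reported model RMSEs — and day-0 records are set to
exactly 100, mirroring percent-of-initial normalization. A second generator
draws from the dummy-coded linear model (default 100 − 8t − 1.3T + offsets)
for MLR recovery, since under the kinetic generator a treatment dummy has no
well-defined true β. `recovery_study` repeats generate → refit over seeded
runs (seed + run index) and reports bias, SD and RMSE per parameter;
individual fit failures are recorded, not fatal.

What the generator does *not* emulate: replicate correlation, heteroscedastic
or proportional noise, assay floor/ceiling effects, lipid-oxidation
covariates, and microbial spoilage. Passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to real-matrix artefacts.

## Problem sizes and numerical choices

Recovery studies in the tests use 200 runs of the full 14-treatment design
(the scale at which Monte-Carlo means stabilize well below the 5 % acceptance
band); the CI-coverage check uses 1000 seeds of a reduced two-treatment
design. Zero-variance series score R² = 1 only when residuals are numerically
zero. Rank checks precede every OLS solve. All randomness flows through
`numpy.random.default_rng` seeds; no global state is touched.

## Known limitations

* Kinetic orders other than zero are out of scope, as are other secondary
  models (Ratkowsky, Eyring) and confidence bands on predictions.
* The published replicate-level raw data are unavailable, so replicate-level
  statistics (parameter SDs, pooled replicate RMSE/CV, the exact MLR table)
  can only be recovered in distribution via the synthetic generator, not
  value-for-value.
* The ensemble reproduces the training protocol, not the original software's
  exact errors, which depend on its initializer and the unpublished data.
* RBF networks are not implemented; retained published networks are all MLPs.
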