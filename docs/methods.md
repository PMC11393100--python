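# Methods

## Problem and model

Dissolved oxygen (DO) in a tidal river is driven by processes on well-separated
time scales: an annual cycle (cold water holds more oxygen, so DO is high in
winter and low in summer), a half-day tidal oscillation, and fast fluctuations
from mixing, biology and pollution events. The package separates the slow,
quasi-deterministic part (the *trend*) from the fast fluctuations and models
the fluctuation statistics superstatistically: locally the fluctuations are
Gaussian with some inverse variance `beta_hat`, but `beta_hat` itself drifts
on a much longer time scale. When `beta_hat` is chi-square distributed with
`n` degrees of freedom and mean `beta0_hat`, the marginal fluctuation density
is exactly the q-Gaussian

    p(x) = C_q^{-1} [1 + (q-1) beta (x - mu)^2]^{1/(1-q)},

with `q = 1 + 2/(n+1)` and `beta = beta0_hat (n+1)/(2n)`. `q` controls tail
weight (Gaussian at `q = 1`, power-law tails with exponent `2/(q-1)`
otherwise, variance infinite for `q >= 5/3`, normalisable for `q < 3`);
`beta` is an inverse-squared-width. The q-Gaussian is an affinely rescaled
Student-t with `nu = (3-q)/(q-1)` degrees of freedom, which gives exact
sampling and CDF evaluation; tests verify the closed-form normalisation
constant, variance and the mixture identity against adaptive quadrature.

## Detrending

Four variants, crossing two decompositions with two trend estimators:

* **additive** `y = T + F` versus **multiplicative** `y = T * F`. All
  multiplicative paths are computed by detrending `log y` additively and
  exponentiating back, so `multiplicative(y) == exp(additive(log y))` holds
  exactly, for the moving-average method as well as for EMD. Multiplicative
  detrending therefore requires strictly positive input, which QC guarantees
  for DO.
* **seasonal** (moving average): a centred moving average with filter
  frequency `f` hours (window `round(60 f / step)` samples, forced odd). At
  the boundaries the window shrinks symmetrically instead of padding, so the
  output is defined everywhere, the estimator is exactly centred at every
  sample, and linear signals pass through unchanged; padding schemes
  fabricate data that contaminates the fluctuation tails.
* **EMD**: empirical mode decomposition by cubic-spline envelope sifting with
  mirrored-extrema boundary extension. IMFs are reported slow-to-fast; the
  trend is the sum of the slow IMFs (plus, by default, the non-oscillatory
  residue) and the fluctuation is the sum of the `m` fastest. The default
  `residue_to="trend"` keeps fluctuations centred near 0 (additive) or 1
  (multiplicative); the alternative `residue_to="fluctuation"` folds the
  residue into `F` instead and is available for comparison.

Sifting stops when the Cauchy-type energy criterion
`sum(m^2)/sum(h^2) < 0.2` is met **and** the candidate has satisfied the IMF
property (`|#extrema - #zero-crossings| <= 1`) for two consecutive
iterations, with a 50-iteration cap. The energy criterion alone terminates
after a single sift whenever a strong tone remains in the candidate (the
tone dominates the denominator), which splits the half-day tidal mode across
two IMFs and leaks it into the fluctuation band; the zero-crossing streak is
the standard guard against this and restores a clean tone/noise split on the
synthetic fixture.

Remainder noise is never removed: every variant reconstructs the input
exactly (to floating tolerance), with the remainder folded into the
fluctuation.

Defaults `f = 6 h` and `m = 3` give a trend that follows the tidal
oscillation while leaving sub-tidal fluctuations; both are per-call
configurable since the appropriate `m` depends on each record's mode count.

## Fitting and model selection

`fit_qgauss_mle` maximises the exact q-Gaussian likelihood over
`(q, beta, mu)` with `q` in `[1+1e-6, 3-1e-3]` and `beta` in
`[1e-12, 1e12]`. The `(q, beta)` surface is ridge-shaped, so the fit first
profiles `beta` analytically (root of the scaled score, solved by Brent) on
a coarse `q` grid with `mu` at the sample median, then polishes all three
parameters with bounded Nelder-Mead and re-profiles `beta` at the optimum.
Solutions on the parameter box are reported with `converged = False` rather
than silently; Gaussian-like samples legitimately pin `q` at the lower
bound.

`compare_detrending_loglik` centres each variant's fluctuation sample
(subtract the mean for additive; divide by the mean and subtract 1 for
multiplicative, so both modes feed zero-centred samples), fits by MLE, and
ranks variants by mean per-observation log-likelihood. Per-observation
means make variants with different effective sample sizes comparable. Two
caveats are intentional: (i) comparing additive and multiplicative
likelihoods on their own fluctuation scales is a model-selection heuristic,
not a likelihood-ratio test — no change-of-variables Jacobian is applied,
so part of the multiplicative advantage comes from the smaller scale of
ratio fluctuations; (ii) `standardize=True` rescales every sample to unit
variance first, making the comparison shape-only. The control experiment
(additive Gaussian noise injected instead of multiplicative mixtures) uses
the standardized comparison, under which additive variants are not
penalised beyond sampling noise.

## Spatial trends

One `(q, beta)` record per site and variant is regressed on
distance-to-sea with ordinary least squares. Because only a handful of
sites exist, a seeded permutation p-value (10^4 permutations of the
parameter values against the distances) accompanies the asymptotic one.
The estimator was not named in the problem setting; OLS plus permutation
inference is the minimal defensible choice.

## Forecasting baselines

The feature matrix has exactly fourteen covariates: the seven measured
channels, hour-of-day / day-of-week / month-of-year mapped affinely onto
[-0.5, 0.5] (`hour/23 - 0.5`, `weekday/6 - 0.5`, `(month-1)/11 - 0.5`), and
sine/cosine of the half-day phase (minutes since the last 00:00 or 12:00,
over 720) and of the elapsed-year fraction (leap-aware). The two
trigonometric pairs encode the two dominant spectral lines of tidal-river
DO, which `fft_dominant_frequencies` recovers from the data (full-length
periodogram for line location; optional Welch averaging when a low-variance
spectrum matters more than resolution).

Windows are built after a chronological 70/20/10 split; normalisation
statistics come from training rows only; no window crosses a split boundary
or a data gap (gaps are detected as timestamp deltas above the nominal
15-minute step); training window order is shuffled under the given seed.

Baselines: **Last** persists the final observed DO; **Repeat** replays the
first `h` values of the 48-step block ending one half-day before the
forecast origin (the literal reading; `alignment="lagged"` gives the
alternative reading, the values exactly one half-day before the forecast
window); **Linear** is a least-squares affine map from the final input
step's fourteen covariates to the `h`-vector of targets. Rank-deficient
linear designs are solved by the minimum-norm SVD solution (exact on
consistent degenerate systems) and flagged; a tiny ridge
(`1e-8 x mean diagonal`) is the fallback for numerically failed solves.

Errors are MAE and SMAPE with denominator `|y| + |yhat|` and no factor 2,
reported in percent; `0/0` terms are defined as 0 (both series agree), a
case that cannot arise on post-QC DO but can on synthetic edge cases.

## Synthetic generator

`generate_site` produces `DO(t) = T(t) * exp(sigma * z_t)` where `T` is a
strictly positive baseline (9 mg/L) plus a winter-high annual cosine
(2 mg/L) and a half-day tidal cosine (1.2 mg/L), and `z_t` is the
chi-square superposition (default `n = 2`, i.e. `q = 5/3`, within the
empirically typical 5/3-2 band for tidal-river DO; mean inverse variance 1;
one `beta_hat` draw per 48 samples). `sigma = 0.035` gives few-percent
relative fluctuations and a fitted `beta` of order 600. `z` is clipped at
`|z| <= 20` so DO never exceeds the 25 mg/L QC ceiling — physically an
oxygen-saturation bound; with these defaults the clip touches only a few
samples per 10^5. Companion channels (temperature anti-correlated with the
DO annual cycle, diel pH, tidal conductivity, lognormal ammonium and
turbidity, gamma-distributed daily rainfall with dry days) are simple
coupled sinusoids plus noise: they exercise feature building and QC, and do
not model river chemistry (no reaeration or metabolism dynamics, no
rainfall-runoff coupling).

`generate_multisite` sets each site's `sigma` to
`sqrt(beta_z / beta_target(d))` with `beta_target = intercept + slope * d`
(defaults 600 and -8 per km over nine sites spanning 3-45 km), so the
fitted `beta` decreases linearly toward inland sites by construction.
Per-site seeds derive from `(seed, distance)`, making the generated
ensemble invariant under permutations of the distance list.

Because the noise enters multiplicatively as a log-q-Gaussian, the
multiplicative-EMD pipeline is the correctly specified model for the
default generator — the model-selection experiment tests whether the
pipeline *finds* that, not whether it is true of any real river. An
additive-noise mode (`sigma = 0` plus externally added noise) supports the
control experiment.

The forecast-ordering fixture (tests) adds a first tidal harmonic and a
diel 24-hour component to the half-day fundamental: a pure single-harmonic
tide is exactly linear in the half-day sin/cos covariates, so the Linear
baseline would interpolate it, and a pure 48-step periodic signal makes
Last statistically indistinguishable from Repeat at a full-period horizon.
Both additions are physically grounded (tidal asymmetry; photosynthesis
cycle) and make the expected Repeat-beats-Last/Linear ordering at
multi-step horizons identifiable. On the default generator site (single
harmonic tide), `analysis/05_forecast_baselines.py` accordingly reports the
Linear baseline as strongest — the fixture and the generator answer
different questions.

## Problem sizes and numerical choices

Simulation sizes are chosen so every check runs comfortably on a single
core: 60-day series for replicate model-selection runs (ranking is stable
at that length), a full 365-day series for end-to-end `q` recovery (at 60
days the MLE sampling scatter of `q` for an infinite-variance `n = 2`
mixture exceeds the +-0.1 recovery band on its own), 90-day series per site
for the nine-site spatial experiment, 2x10^5 samples for the mixture
identity and 10^5 for sampler-recovery grids. Tolerances mirror what the
mathematics supports: 1e-8 relative for closed forms against quadrature,
1e-8 relative reconstruction for detrending (floating-point identities),
+-0.05 on `q` and 10% on `beta` for MLE at those sample sizes.

## Known limitations

* EMD has no convergence theory; mode mixing can reappear for signals whose
  tone-to-noise ratio differs strongly from the fixtures. Ensemble variants
  (EEMD/CEEMDAN) and wavelet detrending are out of scope.
* The superstatistical long time scale is an input (`window_len`), not
  estimated from data.
* The raw log-likelihood comparison across decomposition modes is a
  heuristic (see above); conclusions about real rivers require the
  standardized comparison or an explicit Jacobian treatment.
* The generator's companion channels are caricatures; passing tests show
  the pipeline is internally consistent, not that real sensor data meet its
  assumptions (outages, drift and biofouling are only crudely represented
  by the QC fault injector).
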