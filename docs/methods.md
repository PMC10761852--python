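# Methods

`dendrorecon` implements the standard dendroclimatic reconstruction
workflow — ring widths → chronology → transfer function → reconstructed
seasonal precipitation → extremes and periodicity — together with a
synthetic data generator that provides ground truth for every stage.
This note records the models, the defaults and why they were chosen, and
what the synthetic experiments do and do not demonstrate.

## Chronology model

Each dated ring-width series `w_t` (mm, 0.01 mm recorded precision;
locally absent rings stored as 0.00) is detrended by a **modified
negative exponential** age-trend curve

    f(t) = a·exp(−b·t) + k,   a > 0, b > 0, k ≥ 0,

fitted by constrained least squares over the cambial-age axis
`t = 1..n` (ring index within the core; pith offsets are taken as zero
because no better information is available in general).  The ring-width
index is the **ratio** `w_t / f(t)`, dimensionless with expectation 1 —
the ratio form is preferred over differences because conifer ring-width
variance scales with level.  When the constrained fit is unattainable
(flat or rising growth, a non-positive or effectively non-declining
curve) the fallback is the horizontal mean, which is conservative and
preserves low-frequency variance; a declining straight line can be
selected by configuration.  A fit is treated as degenerate when its
total decline is below 0.1% of the mean width.

**Prewhitening** removes each series' autoregressive persistence before
averaging: an AR(p) model with p chosen by AIC over 0..3 (all candidate
models fitted with `statsmodels.AutoReg`, including the p = 0 null, so
the criteria are on a common likelihood scale).  Residuals are recentred
to mean 1.  The chronology built from prewhitened series is the
*residual* chronology; from raw indices, the *standard* chronology.  The
residual chronology deliberately emphasises interannual variance — a
reconstruction built on it resolves year-to-year and short-cycle
variability well but attenuates multidecadal excursions.

Per-year averaging uses **Tukey's biweight robust mean** (c = 9, median
start, MAD scale, fixed-point iteration to 1e-8), falling back to the
arithmetic mean for fewer than three values where the MAD is degenerate.

Signal strength is tracked with **running Rbar and EPS** over 50-yr
windows advancing 25 yr (community defaults; configurable): Rbar is the
mean pairwise Pearson correlation over series pairs with ≥ 30 common
years in the window, and

    EPS = N·r̄ / (N·r̄ + 1 − r̄)

with N the mean sample depth in the window.  The reconstruction is
truncated at the earliest year from which **every subsequent window**
has EPS ≥ 0.85 — the suffix rule rather than the first crossing, so a
single flickering window cannot extend the reliable span.  Because
prewhitening consumes each series' first p years, the reliable span also
cannot start before the residual chronology exists.

Summary statistics: mean sensitivity `MS = mean |2(x_{t+1}−x_t)/(x_{t+1}+x_t)|`,
standard deviation, and lag-1 autocorrelation.

Regional composites **pool all series into one collection** before
detrending and averaging (one chronology over the union of cores), not
an average of site chronologies; running Rbar for composites uses pooled
pairwise correlations without separating within- from between-site
pairs.  Inter-site coherence is checked separately via pairwise
correlation and PCA on the correlation matrix of site chronologies.

## Cross-dating checks

Dating quality is verified with two classical statistics computed on
detrended, prewhitened, z-scored indices:

- **Gleichläufigkeit** — the proportion of agreeing year-to-year change
  signs; a zero change on either side counts one half.
- **Segment correlations** — each 50-yr segment (25-yr lag) of a series
  is correlated with a leave-one-out biweight master at lags −10..+10;
  a segment is flagged when its lag-0 r falls below the one-tailed
  critical r at α = 0.01, or when a nonzero lag correlates better.
  Sign convention: positive best lag means the series matches the master
  shifted later, i.e. it was dated too old.  The t-value
  `t = r·√((n−2)/(1−r²))` is reported as an auxiliary diagnostic.

Note these flags are not a hypothesis test with an α-level false-alarm
rate: an uncorrelated (undatable) series is flagged nearly everywhere by
construction, and weakly correlated but correctly dated cores produce a
baseline flag rate well above α.

## Growth–climate response

Correlation functions are computed over a 17-month dendroclimatic window
(previous June through current October) plus the named seasons DJF, MAM,
MAMJ, FMAMJ and JJAS.  Significance uses a classical (pairs) bootstrap
with 1000 resamples and a 95% percentile interval; the stationary-block
variant is intentionally not the default.  Monthly p-values are **not**
adjusted for multiplicity — each coefficient is flagged at its own 95%
level, so ~5% of null coefficients will flag by chance.

**Seasonal partial correlations** (seascorr-style) take precipitation as
the primary variable and temperature as secondary, over season lengths
{1, 3, 5, 12} months ending in each calendar month.  The secondary
statistic is the *semi-partial* correlation: the primary is regressed
out of the secondary only, and the residual is correlated with the raw
chronology.  This form measures the secondary's additional association —
it vanishes when the primary saturates the chronology and reduces
exactly to the simple correlation when the two climate variables are
uncorrelated.  Significance comes from empirical non-exceedance
probabilities over 1000 AR(1) surrogate chronologies matched to the
chronology's lag-1 autocorrelation, variance and mean, so the test
respects the chronology's persistence.

Moving correlations use 30-yr windows advancing 2 yr, with per-window
two-tailed significance at 0.05.

## Transfer function and validation

The reconstruction model is simple linear regression of the Feb–Jun
precipitation total on the composite residual chronology over the
calibration era.  Calibration reports r, R², adjusted R², RMSE, F with
its p-value, and the Durbin–Watson statistic of the residuals.

Validation:

- **Leave-one-out cross-validation**: every year predicted from a model
  fitted without it; reports r, R², RMSE, `PRESS = Σ e²_loocv` (mm²),
  and RE computed against the all-years calibration mean — the single-RE
  convention used with LOOCV tables.
- **Split-sample**: fit on one half, verify on the other, both
  directions; the split year defaults to the median calibration year.
  Verification R² is the squared Pearson correlation of observations and
  predictions (it can therefore differ from CE).
- **Skill scores**: `RE = 1 − SSE/SSE(calibration-mean null)` and
  `CE = 1 − SSE/SSE(verification-mean null)`.  RE ≥ CE always (the
  calibration mean is a worse or equal null on the verification period),
  and in-sample RE equals R² exactly for OLS.
- **Sign test**: counts of agreeing first-difference signs with a
  two-tailed binomial p at P = 1/2; pairs with a zero difference on
  either side are dropped, so n−1 pairs at most are scored.
- **Product-mean test** (Fritts' formulation, which names the test but
  fixes no unique denominator; a Welch-type form is used here):
  products `z_t = (obs_t − m_cal)(pred_t − m_cal)` are split into
  positive values and absolute negative values, and
  `t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂)`.  When every product shares one
  sign the test is degenerate (perfect association leaves nothing to
  separate) and is reported as +∞ with a flag rather than a number.

The reconstruction applies the fitted line to the whole truncated
chronology; the uncertainty band is ± 1 calibration RMSE (± 2 RMSE by
configuration).  Negative predicted precipitation is possible under
linear extrapolation and is kept but flagged.

## Variability analysis

- **Low-pass filter**: a cubic smoothing spline whose amplitude response
  is 0.5 at a 10-yr wavelength.  The stiffness is seeded with the
  quartic-filter approximation λ = (T/2π)⁴ and then solved numerically
  against the empirical response on a long grid, so the 50% point is
  exact for the discrete filter rather than the continuous idealisation.
- **Extreme years**: beyond mean ± 1.5 SD of the full reconstructed
  span (not the calibration era), listed most extreme first.
- **Persistent wet/dry periods**: maximal runs of ≥ 2 consecutive years
  whose low-pass value exceeds mean ± 1 SD *of the low-pass series*;
  the 2-yr minimum admits the shortest meaningful episodes while the
  spline already suppresses single-year excursions.
- **Century counts**: extreme-year counts and percentages in 100-yr bins
  from the first reconstructed year; a trailing partial century is
  reported but flagged and excluded from any monotone-trend statement.
- **Multitaper spectrum**: DPSS tapers with time–bandwidth NW = 2 and
  K = 3 tapers (a standard short-series compromise between resolution
  and variance), eigenvalue-weighted, density-normalized so the
  integrated power equals the series variance.  The null continuum is
  the theoretical AR(1) spectrum at the series' lag-1 autocorrelation,
  scaled to the mean estimated power; 95%/99% levels scale it by
  χ²(2K)/2K.  Significant peaks are local maxima above a level,
  reported as periods.
- **Morlet wavelet** (ω₀ = 6, Torrence–Compo conventions): FFT-based
  CWT on a zero-padded grid, scales s₀·2^(j/4) from 2 yr up to a third
  of the series length, Fourier period ≈ 1.03·scale, cone of influence
  at the √2·scale e-folding distance.  The kernel is normalized so white
  noise of variance σ² has expected power σ² at every scale; pointwise
  95% significance compares power to χ²(2)/2-scaled AR(1) red noise.
  The global spectrum keeps the pointwise bound (conservative for the
  localization statements the package makes).

## Synthetic study conditions

The generator emulates the target setting rather than any particular
archive: a **westerly-regime station climate** with 460 mm/yr mean
precipitation of which 80% falls November–May, 17 °C annual mean
temperature with an annual cycle, interannual AR(1) persistence
(φ = 0.25) on a multiplicative annual anomaly with 22% coefficient of
variation, 5% multiplicative monthly jitter, and injected quasi-cycles
at 2.7 and 8.2 yr (amplitude 0.35 × interannual SD each) representing
the ENSO-band variability such regions exhibit.  Spring temperature
anomalies are drawn with correlation −0.5 to the precipitation anomaly:
wet springs are cool springs.

The **forest** contains 3 sites × 8 trees × 2 cores with germination
years staggered from ~650 to ~150 yr before present, so sample depth
declines back in time as in a real collection.  Ring width is

    width_t = (a·e^(−b·t) + k) · max(0, 1 + β·z_P(t) + γ·z_T(t) + η_t + ε_t)

with `z_P` the standardized Feb–Jun precipitation total, `z_T` the
standardized spring temperature, η an AR(1) (φ_b = 0.3) disturbance of
SD 0.25 shared by a tree's cores, and ε per-core noise of SD 0.15.
Noise enters multiplicatively and is truncated at zero, mirroring the
ratio-detrending model downstream.  γ = −0.12 builds in the
moisture-stress structure (positive precipitation, negative temperature
response).  A configuration whose multiplier would clip at zero in more
than 1% of years is rejected outright.

β is set by a **calibration-targeting routine**: treating the site-mean
index as `1 + β·z_P + γ·z_T + noise/√N`, the population correlation with
`z_P` is

    r(β) = (β + γρ) / √(β² + γ² + 2βγρ + s²_mean),

inverted by root-finding for the target r = 0.73 over a 54-yr
calibration era (1965–2018 analogue).  Realized calibration R² then
scatters around ~0.50 across seeds: sampling error of r at n = 54 is the
dominant term, and prewhitening attenuates the correlation slightly
because part of the climate signal's own persistence is removed with the
noise persistence.

**What the synthetic experiments show** — that the pipeline recovers
known couplings, spectral content and pre-instrumental climate from data
generated under its own structural assumptions (multiplicative signal on
a smooth age trend, linear climate coupling, AR(1) noise).  **What they
do not show** — robustness to model violations found in real archives:
non-exponential growth releases/suppressions, missing/false rings and
dating error, time-varying climate response (divergence), heteroscedastic
measurement error, or low-frequency variance lost to the detrending
choice.  Passing tests certify internal correctness, not field validity.

## Problem sizes and determinism

The default simulated study spans 719 yr (1300–2018) with 48 core
series; the Monte-Carlo recovery experiments use 50 seeded replicates of
that study (20–30 in the standalone acceptance script), and null
calibrations of the spectral machinery use 200 replicates at n = 256.
These sizes give stable medians and binomial bands while keeping any
single analysis in the seconds-to-minutes range.  Every stochastic
component takes an explicit seed; two runs with equal configuration and
seed are byte-identical, and wall-clock seeding is deliberately
unsupported.

## Known limitations

- RCS, signal-free, spline and basal-area detrending are out of scope
  (the fallback cascade is negexp → mean/line only).
- No variance stabilization for time-varying sample depth.
- The residual-chronology reconstruction attenuates multidecadal
  variability by design; standard-chronology reconstructions are
  possible (`prewhiten: false`) but not the default.
- Wavelet global-spectrum significance keeps the pointwise χ²(2) bound
  rather than the time-averaged degrees-of-freedom correction.
- The seascorr secondary statistic is a semi-partial correlation (see
  above); users expecting the full partial correlation should note the
  difference when both climate variables are strongly collinear.
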