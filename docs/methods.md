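# Methods

`ringclim` implements a complete dendroclimatic workflow: from raw
ring measurements to residual chronologies, and from daily station
temperatures to a bootstrap-tested correlation surface over every
cumulative window of the growth season.  This note records the models,
the numerical choices, and what the synthetic tests do and do not
demonstrate.

## Proxies

**Blue intensity (BI).**  Latewood blue reflectance `x` (8-bit, 0–255)
is inverted to `BI = 2.56 − x/100`, mapping reflectance into
(0, 2.56] so that denser (darker) latewood scores higher.  No scanner
calibration or delta-BI correction is applied.

**Basal area increment (BAI).**  Diameter at breast height is
reconstructed backwards from the coring-year measurement,
`DBH(t−1) = DBH(t) − 2·TRW(t)`, assuming radial symmetry of the single
core, and each ring's area is `BAI(t) = π/4·(DBH(t)² − DBH(t−1)²)`.
Two caveats are inherited from the data model rather than the code:
DBH is used over bark as measured, and no pith-offset estimation is
attempted for cores that miss the pith — the recursion simply stops at
the innermost measured ring.  The implementation enforces the exact
telescoping identity Σ BAI = π/4·(DBH_final² − DBH_innermost²) (tested
to 1e−9 relative) and refuses series whose widths are inconsistent
with the measured DBH (reconstructed diameter ≤ 0).

## Detrending and prewhitening

Ratio indices are used throughout: `standard index = raw / fitted`,
with the fitted curve floored at 1e−4 of the series mean so a
pathological fit cannot blow up the ratio.

**Smoothing spline (TRW, BAI).**  The growth curve is a
second-difference penalized smoother, the discrete form of a cubic
smoothing spline: `(I + λ·D₂ᵀD₂)·s = y`.  Its interior amplitude
response is `H(f) = 1/(1 + 16·λ·sin⁴(πf))`, so the penalty for a 50%
response at a 30-year period has the closed form
`λ = (1/0.5 − 1)/(16·sin⁴(π/30)) ≈ 524`.  An FFT oracle on a 600-year
sinusoid confirms the realized response is 0.500 ± 0.02 at the cutoff
and monotone in frequency.  Constants and straight lines lie in the
penalty null space and are reproduced exactly; detrending is
scale-equivariant.  The sparse banded system is solved directly, O(n).

**Hugershoff curve (BI).**  `a·t^b·e^(−c·t) + d` over cambial ring
index t = 1..n, fit by bounded nonlinear least squares (a > 0, c ≥ 0)
with multi-start initialization (b ∈ {0.1, 0.5, 1, log-linear seed}; c
seeded from a log-linear regression).  Noise-free parameter sets are
recovered to < 1% relative error.  Fallback cascade on non-convergence:
linear trend, then series mean (a constant series short-circuits to the
mean, giving indices ≡ 1).

**AR prewhitening.**  An AR(p) model with p chosen by AIC in
0..max_order (default 10, capped at n/3) is fit to each standard index
series; its residuals form the residual index.  The residual series
keeps the calendar span: the first p positions hold the series mean,
and the whole series is re-centred so its mean equals the
standard-index mean exactly.  Prewhitening is applied per series, not
to the mean chronology — the convention of the standard chronology
toolchain.

## Chronologies and statistics

The master chronology is the year-by-year Tukey biweight robust mean
(tuning constant 9, MAD scale, iterated to 1e−8 or 50 iterations;
arithmetic mean for n ≤ 2, median if the MAD is zero), with no
variance stabilization.  Sample depth is recorded per year.

Reported statistics, computed over the climate-overlap window:

* **AGR ± SD** — mean and SD of the per-series mean growth rates (a
  pooled SD would mix in age-trend variance);
* **Rbar** — mean of all pairwise Pearson correlations of residual
  indices over each pair's overlap (≥ 10 years), un-segmented;
* **EPS** — `n̄·Rbar/(n̄·Rbar + 1 − Rbar)` with n̄ the mean sample
  depth in the window; 0.85 is the conventional reliability threshold;
* **mean sensitivity** — `mean |2(x_{t+1} − x_t)/(x_{t+1} + x_t)|` of
  the residual indices;
* **first-order autocorrelation** — lag-1 Pearson autocorrelation of
  the *raw* series, averaged across trees.

**Crossdating check.**  Each series is spline-detrended and its
50-year segments (25-year overlap) correlated against the biweight
master of the other detrended series (leave-one-out).  Segments below
the one-tailed p < 0.01 critical r (t approximation at the segment
length) are flagged as warnings for inspection, never auto-excluded.

## Daily climate windows

The growth season runs from June 1 of the previous calendar year to
October 31 of the current one.  February 29 is dropped before
gridding, so the season axis is always 518 days (214 previous-year +
304 current-year).  For every width w in 21..120 and every start day
s with s + w − 1 ≤ 518, the window mean temperature is stored per
growth year — 44,850 windows in total.  A window is computed when at
least 95% of its days are present (mean over present days;
configurable); a growth year with no data raises.  One-day effects of
the leap-day rule are negligible against ≥ 21-day means.

A chronology year enters the correlation analysis only when its whole
518-day season is covered: a record starting 1978-01-01 supports
growth years 1979 onward (n = 41 for a 1978–2019 record) even though
the chronology itself is truncated to 1978–2019.

## Bootstrap correlation and stability

For each window the Pearson correlation with the residual chronology
is computed on the original years, and year pairs are resampled with
replacement (1000 replicates by default).  Significance at p < 0.05 is
"the 95% bootstrap interval excludes zero".

* **Interval type.**  The default interval is BCa (bias-corrected
  accelerated, jackknife acceleration).  The plain percentile interval
  is available (`ci_method="percentile"`) but is anti-conservative at
  these sample sizes: in a null simulation (independent normal pairs,
  n = 41, 1000 replicates, ≥ 1500 Monte-Carlo repetitions) the
  percentile rule rejects ~7.1% of the time versus ~5.7% for BCa.
* **Reproducibility.**  The bootstrap stream for each width is derived
  deterministically from (master seed, width) and its resample count
  matrix is shared across the start days of that width; marginal
  per-cell intervals are unaffected, cells of one width become
  computable as three matrix products, and an identical master seed
  reproduces the grid bit for bit.
* **Best window.**  Maximum |r| among significant cells; ties broken
  toward smaller width, then earlier start.  No multiple-testing
  correction is applied across the grid: neighbouring windows share
  most of their days, so the cells are strongly dependent and the grid
  is read as a map, not a family of independent tests.  Any single
  "best" cell should be interpreted with the ridge structure of the
  surface in mind (see limitations).
* **Stability.**  Temporal stability of a chosen window uses plain
  Pearson correlations in 15-year blocks stepped by one year, against
  the two-tailed parametric critical value (|r| = 0.514 at n = 15,
  p < 0.05).  The bootstrap is deliberately not used here, matching
  the parametric critical line convention for short blocks.

## Synthetic data

The generator inverts the analysis: daily temperature is a seasonal
cosine (trough January 15) plus a per-year offset and AR(1) weather
noise; the per-tree growth index is
`1 + β·z_t + u_t + e_{i,t}` where `z_t` is the standardized mean
temperature of one known window, `u_t` an AR(1) year effect shared
within a site, and `e_{i,t}` AR(1) tree noise.  Ring width is the
index times a per-tree-jittered Hugershoff age curve (floored at
0.05 mm); DBH is the doubled ring sum plus a base offset; BI is
generated on its own late-season window and pushed through the inverse
reflectance transform.  β is expressed through a target chronology
correlation r*: the shared-noise SD is solved from
`r*² = β²/(β² + σ_u² + σ_e²/n)`.  Because the tree and shared noise
carry AR memory while the signal is near-white, prewhitening removes
proportionally more noise than signal, so the realized correlation of
the *residual* chronology typically exceeds r* somewhat.

Defaults emulate a mid-elevation Carpathian Norway spruce study
system: 50 trees per elevation class, series 68–135 years ending 2019,
climate record exposed from 1978; annual mean 5.4 °C, amplitude
11.4 °C (January ≈ −6 °C, July ≈ +16.5 °C), daily AR(1) 0.65 with
stationary SD 3.5 °C, interannual SD 0.4 °C; a 60-day winter signal
window (Dec 1 – Jan 29) for ring width and a 59-day late-summer window
(Aug 15 – Oct 12) for blue intensity, each at r* = 0.55.  The noise
and age-curve parameters were calibrated once against the published
ranges for such stands — raw lag-1 autocorrelation ≈ 0.87 (TRW) and
≈ 0.54 (BI), mean sensitivity ≈ 0.18 (TRW) and ≈ 0.08 (BI), Rbar
0.15–0.35, EPS > 0.85, mean ring width ≈ 1.9 mm, mean BI ≈ 2.0 — and
then frozen.

What the generator does **not** emulate: missing and false rings,
measurement error, disturbance pulses and releases, stand dynamics,
elevation-dependent climate response, heteroscedastic juvenile
variance, and any process-based growth physiology.  Passing tests
therefore demonstrate that the pipeline recovers a known multiplicative
signal under realistic noise magnitudes and memory — not that it
handles every pathology of real wood.

## Known limitations

* **Best-window identifiability.**  The |r| surface over (start,
  width) has a flat ridge along nested and overlapping windows: a
  window containing the true signal window retains most of the signal
  while averaging down noise, so with ~41 years its sample correlation
  is frequently within sampling error of the truth's.  In replicate
  experiments at r* = 0.55 the best cell overlaps the true window
  ~95% of the time, but matches its start to ±10 days *and* width to
  ±15 days only ~60% of the time, with width errors dominating.
  Reported best windows should be read as a neighbourhood, not a
  point estimate.
* Percentile-bootstrap significance (if selected) is anti-conservative
  at n ≈ 41; the BCa default mitigates but does not perfectly
  nominalize the rate (~5.7% measured).
* RWL export rounds to the dialect precision (0.001 or 0.01 mm);
  round-trips are exact only to that precision.
* The AR order search is unstable below ~30 years (a warning is
  issued); chronologies built from very short series should be
  prewhitened with care.

## Problem sizes used in the test suite

The unit and property tests run on series of 40–600 years and 2–50
trees.  The end-to-end recovery experiment uses the full default
scenario (50 trees, 42-year truncation, 41 analysis years, 1000
bootstrap replicates, 50 replicates); the null-calibration experiment
uses 2000 Monte-Carlo repetitions of n = 41 pairs with 1000 bootstrap
replicates each.  Integration tests use a reduced scenario (12 trees
per class, 60–90-year series) and 150–300 bootstrap replicates.
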