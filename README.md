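# ringclim

Tree-ring chronologies and daily-resolution climate–growth correlation.

`ringclim` is for dendroclimatologists who want to ask, without being
tied to calendar months: *which stretch of the year's temperatures does
a stand of trees actually record?*  It builds residual chronologies
from three ring proxies — ring width (TRW, mm), basal area increment
(BAI, mm²) and latewood blue intensity (BI) — and correlates them with
daily mean temperature over **every** cumulative window of 21–120 days
across the growth season (June 1 of the previous year through October
31 of the current one), with bootstrap significance and 15-year
moving-window stability.

## The method in brief

Per tree, raw measurements are converted to dimensionless indices by
ratio detrending, `I_t = w_t / f(t)`, where `f` is a cubic smoothing
spline with a 50% frequency cutoff at 30 years (TRW, BAI) or a
Hugershoff curve `a·t^b·e^{−ct} + d` (BI, whose juvenile rise the
spline would chase).  Remaining serial memory is removed with an AR(p)
model (p by AIC), and the residual indices are averaged year by year
with a Tukey biweight robust mean into the site chronology.  Quality is
summarised by the classical statistics: mean inter-series correlation
(Rbar), expressed population signal `EPS = n̄·Rbar/(n̄·Rbar + 1 −
Rbar)`, mean sensitivity, and the raw series' first-order
autocorrelation.

Supporting pieces: `BI = 2.56 − x/100` inverts 8-bit blue reflectance;
`DBH(t−1) = DBH(t) − 2·TRW(t)` reconstructs diameters backwards from
the coring-year DBH and `BAI_t = π/4·(DBH_t² − DBH_{t−1}²)` converts
them to area increments; a COFECHA-style check correlates detrended
50-year segments against a leave-one-out master to flag dating errors.

The chronology is then correlated with the mean temperature of every
(start day, width) window on a 518-day season axis (Feb 29 dropped).
Each correlation gets a bootstrap confidence interval (year pairs
resampled with replacement, n = 1000; BCa interval by default) and is
called significant at p < 0.05 when the interval excludes zero.  The
best window — maximum |r| among significant cells — is reported with a
calendar label, and its correlation is traced through 15-year running
windows against the parametric critical value (|r| = 0.514 at n = 15).

Because the study data this workflow targets are not publicly
deposited, the package ships a first-class synthetic generator
(`ringclim.synthetic`) that emulates the study system — two elevation
classes of 50 Norway-spruce-like trees, 68–135-year series, daily
temperatures with a Carpathian seasonal cycle — and injects a known
climate signal (default: a 60-day winter window for TRW at a
chronology-level correlation of 0.55, a 59-day late-summer window for
BI), so every stage is testable against ground truth.

## Worked example

```python
import numpy as np
from ringclim import (SyntheticScenario, simulate_scenario, detrend_dataset,
                      build_chronology, chronology_stats, truncate_common_period,
                      build_season_grid, correlate_grid, moving_stability)

scenario = SyntheticScenario(seed=1)            # 50 trees per elevation class
dataset, trees, reflectance, climate, truth = simulate_scenario(scenario)

high = dataset.by_elevation("high")             # 50 ring-width series
indices = detrend_dataset(high)                 # spline + AR prewhitening
chron = truncate_common_period(build_chronology(indices), climate)
stats = chronology_stats(high, indices, window=(chron.first_year, chron.last_year))
print(f"chronology {chron.first_year}-{chron.last_year}, "
      f"AGR {stats.agr:.2f} +/- {stats.agr_sd:.2f} mm, Rbar {stats.rbar:.3f}, "
      f"MS {stats.mean_sens:.3f}, EPS {stats.eps:.3f}")

years = np.arange(1979, 2020)                   # growth years with full season coverage
grid = build_season_grid(climate, years)
result = correlate_grid(chron.clip(1979, 2019), grid, n_boot=1000, seed=1)
best = result.best()
print(f"best window: {result.best_label()} (start day {result.best_cell[0]}, "
      f"{result.best_cell[1]} days), r = {best.r:.3f}, "
      f"95% CI [{best.ci_low:.3f}, {best.ci_high:.3f}], n = {best.n_years}")

stability = moving_stability(chron.clip(1979, 2019), grid.window_series(*result.best_cell))
print(f"moving correlation: {len(stability.r)} 15-year windows, "
      f"{int(stability.significant.sum())} significant (critical |r| = {stability.critical_r:.3f})")
```

Output:

```
chronology 1978-2019, AGR 1.87 +/- 0.17 mm, Rbar 0.264, MS 0.178, EPS 0.947
best window: dec 2 – Feb 1 (start day 185, 62 days), r = 0.663, 95% CI [0.476, 0.791], n = 41
moving correlation: 27 15-year windows, 26 significant (critical |r| = 0.514)
```

Reading it: the 50-tree chronology is reliable (EPS 0.95, well above
the 0.85 convention) with a common-signal share (Rbar 0.26) typical of
temperate spruce.  The correlation sweep finds its strongest
significant window on December 2 – February 1 (62 days), essentially
the injected December 1 – January 29 signal window (start day 184,
60 days), and the relationship is stable through time — 26 of 27
running 15-year windows clear the significance line.  Best windows
should be read as a neighbourhood rather than a point: windows nested
in or containing the true one carry almost the same correlation (see
`docs/methods.md`).

The same workflow runs from the shell on any RWL + CSV data set:

```
ringclim simulate --seed 1 --out data/
ringclim run --trw data/trw.rwl --climate data/climate.csv \
             --trees data/trees.csv --reflectance data/reflectance.csv \
             --seed 1 --out run/
```

which writes per-proxy chronologies, a summary-statistics CSV,
correlation-grid and stability CSVs, heat-map plots, a best-window
report, and a manifest that makes the run bit-reproducible.

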