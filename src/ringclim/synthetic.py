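"""Synthetic ring and climate data with a known injected temperature signal.

The generator is the inverse of the analysis pipeline: it draws daily
temperatures with a seasonal cycle, interannual variation and AR(1)
weather noise, then builds per-tree ring series whose dimensionless
growth index responds linearly to the mean temperature of one known
multi-week window,

    index_t = 1 + beta * z_t + u_t + e_{i,t},

where ``z_t`` is the standardized window-mean temperature of growth
year t, ``u_t`` an AR(1) year effect shared by all trees of a site
(non-climatic common variance: stand dynamics, disturbance), and
``e_{i,t}`` AR(1) tree-level noise.  Raw ring width is the index times
a per-tree Hugershoff age curve, floored at 0.05 mm; blue intensity is
generated the same way on its own (late-season) window and pushed
through the inverse of the reflectance transform, so the analysis-side
transform recovers it exactly.

Because the signal acts multiplicatively on the index, ratio
detrending recovers it by construction; the generator's purpose is to
give every pipeline stage a ground truth: the true window, the true
population correlation, and calibration targets for the chronology
statistics (inter-series correlation ~0.3, raw lag-1 autocorrelation
~0.5-0.9, EPS > 0.85 at 50 trees).

Default magnitudes emulate the study system the package is built
around: mid-elevation Carpathian Norway spruce with ~50 cores per
elevation class, series 68-135 years long ending in 2019, a mean
annual temperature near 5.4 deg C with January near -6 and July near
+16.5, and a chronology-level signal of r ~ 0.55 on a 60-day winter
window (ring width) and a 59-day late-summer window (blue intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate_windows import SEASON_LENGTH, _season_daily_matrix
from .proxies import BlueReflectanceSeries
from .ring_io import DailyClimate, RingDataset, RingSeries, TreeRecord

__all__ = [
    "ClimateParams",
    "SyntheticScenario",
    "SyntheticTruth",
    "simulate_daily_temperature",
    "simulate_ring_dataset",
    "simulate_scenario",
]


@dataclass(frozen=True)
class ClimateParams:
    """Daily temperature model: seasonal cycle + year effect + AR(1) noise.

    The cycle troughs on January 15; ``annual_mean`` and ``amplitude``
    are in deg C, ``daily_sd`` is the stationary SD of the AR(1)
    weather noise, ``interannual_sd`` the SD of the calendar-year
    offset.
    """

    annual_mean: float = 5.4
    amplitude: float = 11.4
    daily_ar: float = 0.65
    daily_sd: float = 3.5
    interannual_sd: float = 0.4


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one two-elevation study data set.

    ``signal_window`` / ``bi_signal_window`` are (season start day,
    width in days) on the 518-day growth-season axis; the defaults are
    a winter window (Dec 1 - Jan 29) for ring width and a late-summer
    window (Aug 15 - Oct 12) for blue intensity.  ``signal_r`` is the
    target population correlation between the site chronology and the
    window-mean temperature; the per-tree effect size beta and the
    shared-noise SD are derived from it.
    """

    n_trees: int = 50  # per elevation class
    last_year: int = 2019
    length_range: tuple[int, int] = (68, 135)
    climate_start_year: int = 1978
    climate: ClimateParams = field(default_factory=ClimateParams)

    signal_window: tuple[int, int] = (184, 60)  # dec 1 (prev) .. Jan 29
    signal_r: float = 0.55
    beta: float = 0.06  # index change per SD of window-mean temperature
    ar_phi: float = 0.65
    tree_noise_sd: float = 0.20

    bi_signal_window: tuple[int, int] = (441, 59)  # Aug 15 .. Oct 12
    bi_signal_r: float = 0.55
    bi_beta: float = 0.022
    bi_ar_phi: float = 0.35
    bi_tree_noise_sd: float = 0.06

    trw_curve: tuple[float, float, float, float] = (1.8, 0.9, 0.2, 1.5)
    bi_curve: tuple[float, float, float, float] = (0.35, 0.9, 0.25, 2.05)
    dbh_base: float = 60.0  # mm added over the doubled ring sum (pith offset, bark)
    trw_floor: float = 0.05  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        for window in (self.signal_window, self.bi_signal_window):
            start, width = window
            if not (1 <= start and start + width - 1 <= SEASON_LENGTH):
                raise ValueError(f"signal window {window} runs outside the 518-day season")
        if not (0 <= self.signal_r < 1 and 0 <= self.bi_signal_r < 1):
            raise ValueError("target correlations must lie in [0, 1)")
        if min(self.tree_noise_sd, self.bi_tree_noise_sd, self.climate.daily_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    def shared_noise_sd(self, beta: float, target_r: float, tree_sd: float) -> float:
        """SD of the shared year effect that puts the chronology-level
        correlation with the window temperature at ``target_r``."""
        if target_r == 0.0:
            return abs(beta) * 1.5 if beta else 0.05
        total = beta**2 * (1.0 / target_r**2 - 1.0)
        var = total - tree_sd**2 / self.n_trees
        if var <= 0:
            raise ValueError("target correlation unreachable: tree noise alone exceeds the budget")
        return float(np.sqrt(var))


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated data set, for test harnesses."""

    signal_window: tuple[int, int]
    bi_signal_window: tuple[int, int]
    signal_r: float
    bi_signal_r: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "trw_window_start": self.signal_window[0],
            "trw_window_width": self.signal_window[1],
            "bi_window_start": self.bi_signal_window[0],
            "bi_window_width": self.bi_signal_window[1],
            "trw_target_r": self.signal_r,
            "bi_target_r": self.bi_signal_r,
            "seed": self.seed,
        }


def _ar1(rng: np.random.Generator, n: int, phi: float, stationary_sd: float) -> np.ndarray:
    """Stationary AR(1) path of length n with the given marginal SD."""
    if stationary_sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = stationary_sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal(0.0, stationary_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_daily_temperature(
    scenario: SyntheticScenario,
    first_year: int | None = None,
    last_year: int | None = None,
    station_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> DailyClimate:
    """Daily mean temperatures from ``first_year``-01-01 to ``last_year``-12-31.

    T(d) = annual_mean - amplitude * cos(2 pi (doy - 15) / 365.25)
           + year effect + AR(1) daily noise; identical seeds give
    identical series.
    """
    p = scenario.climate
    first_year = scenario.climate_start_year if first_year is None else first_year
    last_year = scenario.last_year if last_year is None else last_year
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 11]))
    dates = pd.date_range(f"{first_year}-01-01", f"{last_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = p.annual_mean - p.amplitude * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)
    years = dates.year.to_numpy()
    uniq = np.arange(first_year, last_year + 1)
    offsets = rng.normal(0.0, p.interannual_sd, size=len(uniq)) if p.interannual_sd else np.zeros(len(uniq))
    year_effect = offsets[years - first_year]
    noise = _ar1(rng, len(dates), p.daily_ar, p.daily_sd)
    return DailyClimate(station_id, dates, seasonal + year_effect + noise)


def _window_z(climate: DailyClimate, years: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Standardized window-mean temperature per growth year."""
    start, width = window
    daily = _season_daily_matrix(climate, years)
    chunk = daily[:, start - 1 : start + width - 1]
    if np.any(~np.isfinite(chunk)):
        raise ValueError("signal window not fully covered by the climate record")
    means = chunk.mean(axis=1)
    sd = means.std()
    if sd == 0:
        raise ValueError("window-mean temperature has zero variance")
    return (means - means.mean()) / sd


def simulate_ring_dataset(
    scenario: SyntheticScenario,
    climate: DailyClimate,
    rng: np.random.Generator | None = None,
) -> tuple[RingDataset, dict[str, TreeRecord], list[BlueReflectanceSeries], SyntheticTruth]:
    """Generate TRW series, tree records and raw BI reflectance for both
    elevation classes, driven by ``climate`` (which must cover every
    ring year plus the preceding June)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 23]))
    last = scenario.last_year
    lo_len, hi_len = scenario.length_range
    n = scenario.n_trees

    all_years = np.arange(last - hi_len + 1, last + 1)
    if climate.dates[0] > pd.Timestamp(int(all_years[0]) - 1, 6, 1) or climate.dates[-1] < pd.Timestamp(
        last, 10, 31
    ):
        raise ValueError("climate record does not cover the ring years plus the previous June")
    z_trw = _window_z(climate, all_years, scenario.signal_window)
    z_bi = _window_z(climate, all_years, scenario.bi_signal_window)

    sd_u = scenario.shared_noise_sd(scenario.beta, scenario.signal_r, scenario.tree_noise_sd)
    sd_u_bi = scenario.shared_noise_sd(scenario.bi_beta, scenario.bi_signal_r, scenario.bi_tree_noise_sd)

    series: list[RingSeries] = []
    trees: dict[str, TreeRecord] = {}
    reflectance: list[BlueReflectanceSeries] = []

    for cls, agr_factor in (("low", 1.1), ("high", 0.9)):
        # non-climatic year effects shared within the elevation class
        u_trw = _ar1(rng, len(all_years), scenario.ar_phi, sd_u)
        u_bi = _ar1(rng, len(all_years), scenario.bi_ar_phi, sd_u_bi)
        lengths = rng.integers(lo_len, hi_len + 1, size=n)
        for k in range(n):
            sid = f"{cls[0].upper()}{k + 1:03d}"
            length = int(lengths[k])
            first = last - length + 1
            sl = slice(len(all_years) - length, len(all_years))
            t = np.arange(1, length + 1, dtype=float)

            a, b, c, d = scenario.trw_curve
            a_i = a * agr_factor * np.exp(rng.normal(0.0, 0.15))
            d_i = max(d + rng.normal(0.0, 0.1), 0.1)
            curve = a_i * t**b * np.exp(-c * t) + d_i
            e = _ar1(rng, length, scenario.ar_phi, scenario.tree_noise_sd)
            index = 1.0 + scenario.beta * z_trw[sl] + u_trw[sl] + e
            trw = np.maximum(curve * index, scenario.trw_floor)
            series.append(RingSeries(sid, first, trw, "TRW"))

            dbh = 2.0 * float(trw.sum()) + scenario.dbh_base * np.exp(rng.normal(0.0, 0.1))
            trees[sid] = TreeRecord(sid, dbh, cls)

            ab, bb, cb, db = scenario.bi_curve
            ab_i = ab * np.exp(rng.normal(0.0, 0.1))
            curve_bi = ab_i * t**bb * np.exp(-cb * t) + db
            e_bi = _ar1(rng, length, scenario.bi_ar_phi, scenario.bi_tree_noise_sd)
            index_bi = 1.0 + scenario.bi_beta * z_bi[sl] + u_bi[sl] + e_bi
            bi = np.clip(curve_bi * index_bi, 0.01, 2.56)
            refl = np.clip((2.56 - bi) * 100.0, 0.0, 255.0)
            reflectance.append(BlueReflectanceSeries(sid, first, refl))

    dataset = RingDataset(series=series, trees=trees, proxy_kind="TRW")
    truth = SyntheticTruth(
        scenario.signal_window,
        scenario.bi_signal_window,
        scenario.signal_r,
        scenario.bi_signal_r,
        scenario.seed,
    )
    return dataset, trees, reflectance, truth


def simulate_scenario(
    scenario: SyntheticScenario,
) -> tuple[RingDataset, dict[str, TreeRecord], list[BlueReflectanceSeries], DailyClimate, SyntheticTruth]:
    """Full study data set: ring data plus the station's climate record.

    Internally the climate is simulated over the whole ring span (the
    signal has to exist for every ring year); the returned record, like
    a real station's, starts at ``scenario.climate_start_year``.
    """
    hi_len = scenario.length_range[1]
    sim_first = scenario.last_year - hi_len  # covers previous June of the oldest ring
    climate_full = simulate_daily_temperature(scenario, sim_first, scenario.last_year)
    dataset, trees, reflectance, truth = simulate_ring_dataset(scenario, climate_full)
    keep = climate_full.dates.year >= scenario.climate_start_year
    climate = DailyClimate(
        climate_full.station_id, climate_full.dates[keep], climate_full.tmean[keep]
    )
    return dataset, trees, reflectance, climate, truth
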