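"""Master chronologies and the classical dendrochronological statistics.

A chronology is the year-by-year robust (Tukey biweight) mean of the
per-tree index series, carrying its sample depth.  The quality
statistics summarise how much common signal the trees share:

* ``rbar`` — mean of all pairwise inter-series Pearson correlations;
* ``EPS`` — expressed population signal, ``n*rbar / (n*rbar + 1 - rbar)``
  with n the mean sample depth; the conventional reliability threshold
  is 0.85;
* mean sensitivity — mean absolute relative year-to-year change,
  ``|2(x_{t+1} - x_t) / (x_{t+1} + x_t)|``;
* first-order autocorrelation of the raw series (temporal memory).

A COFECHA-style crossdating check correlates detrended 50-year
segments (25-year overlap) of each series against the leave-one-out
master and flags segments below the one-tailed p < 0.01 critical
correlation.  Flags are warnings for inspection, never automatic
exclusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .detrend import DetrendConfig, IndexSeries, spline_fit, to_standard_index
from .ring_io import DailyClimate, RingDataset, RingSeries

__all__ = [
    "Chronology",
    "ChronologyStats",
    "SegmentCheck",
    "biweight_mean",
    "build_chronology",
    "mean_sensitivity",
    "rbar_and_eps",
    "chronology_stats",
    "crossdating_check",
    "truncate_common_period",
]

BIWEIGHT_C = 9.0
EPS_THRESHOLD = 0.85


@dataclass
class Chronology:
    """Year-indexed master index series with per-year sample depth."""

    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        self.sample_depth = np.asarray(self.sample_depth, dtype=int)
        if not (len(self.years) == len(self.index) == len(self.sample_depth)):
            raise ValueError("years, index and sample_depth must have equal length")
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError("chronology years must be consecutive")
        if np.any(self.sample_depth < 1):
            raise ValueError("sample depth must be >= 1 wherever the index is defined")

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def clip(self, first: int, last: int) -> "Chronology":
        m = (self.years >= first) & (self.years <= last)
        if not m.any():
            raise ValueError(f"chronology has no years in [{first}, {last}]")
        return Chronology(self.years[m], self.index[m], self.sample_depth[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "index": self.index, "sample_depth": self.sample_depth}
        )


@dataclass
class ChronologyStats:
    """Descriptive statistics of one chronology's constituent series."""

    n_series: int
    length_mean: float
    length_min: int
    length_max: int
    agr: float
    agr_sd: float
    rbar: float
    mean_sens: float
    auto_corr: float
    eps: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def eps_from_rbar(n_bar: float, rbar: float) -> float:
    """Expressed population signal n*rbar / (n*rbar + 1 - rbar)."""
    if rbar == 1.0:
        return 1.0
    return float(n_bar * rbar / (n_bar * rbar + 1.0 - rbar))


def biweight_mean(values: np.ndarray) -> float:
    """Tukey biweight robust location (tuning constant 9, MAD scale).

    Iterated to 1e-8 or 50 iterations; degenerates to the arithmetic
    mean for n <= 2 and to the median when the MAD is zero.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight_mean of an empty sample")
    if x.size <= 2:
        return float(x.mean())
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return float(med)
    loc = float(med)
    for _ in range(50):
        u = (x - loc) / (BIWEIGHT_C * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0.0:
            break
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - loc) < 1e-8:
            return new
        loc = new
    return loc


def _align(indices: list[IndexSeries], which: str = "residual") -> pd.DataFrame:
    """Year x series matrix of index values (NaN outside coverage)."""
    cols = {}
    for s in indices:
        vals = s.residual_index if which == "residual" else s.standard_index
        cols[s.series_id] = pd.Series(vals, index=s.years)
    return pd.DataFrame(cols)


def build_chronology(indices: list[IndexSeries], which: str = "residual") -> Chronology:
    """Per-year biweight mean over all series covering that year."""
    if len(indices) < 2:
        raise ValueError("need at least 2 series to build a chronology")
    frame = _align(indices, which)
    depth = frame.notna().sum(axis=1)
    if (depth >= 2).sum() == 0:
        raise ValueError("series have no overlapping years")
    years = frame.index[depth >= 1]
    if np.any(np.diff(years) != 1):
        raise ValueError("combined series coverage has calendar gaps")
    index = np.array([biweight_mean(frame.loc[y].dropna().to_numpy()) for y in years])
    return Chronology(np.asarray(years), index, depth.loc[years].to_numpy())


def mean_sensitivity(series: np.ndarray) -> float:
    """Mean |2(x_{t+1}-x_t)/(x_{t+1}+x_t)| over adjacent years."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("mean_sensitivity needs at least 2 values")
    if np.any(x < 0):
        raise ValueError("mean_sensitivity expects non-negative values")
    s = x[1:] + x[:-1]
    if np.any(s == 0):
        raise ValueError("adjacent values sum to zero; mean sensitivity undefined")
    return float(np.mean(np.abs(2.0 * (x[1:] - x[:-1]) / s)))


def rbar_and_eps(
    indices: list[IndexSeries],
    window: tuple[int, int] | None = None,
    which: str = "residual",
    min_overlap: int = 10,
) -> tuple[float, float]:
    """Mean inter-series correlation and expressed population signal.

    ``rbar`` is the mean of all pairwise Pearson correlations computed
    over each pair's overlapping years within ``window``; EPS uses the
    mean sample depth over the window.
    """
    frame = _align(indices, which)
    if window is not None:
        frame = frame.loc[(frame.index >= window[0]) & (frame.index <= window[1])]
    if frame.shape[1] < 2 or frame.empty:
        raise ValueError("need >= 2 series with coverage in the window")
    cols = frame.columns
    rs = []
    for i in range(len(cols)):
        xi = frame[cols[i]]
        for j in range(i + 1, len(cols)):
            pair = pd.concat([xi, frame[cols[j]]], axis=1).dropna()
            if len(pair) < min_overlap:
                continue
            a = pair.iloc[:, 0].to_numpy()
            b = pair.iloc[:, 1].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    if not rs:
        raise ValueError(f"no series pair overlaps >= {min_overlap} years")
    rbar = float(np.mean(rs))
    n_bar = float(frame.notna().sum(axis=1).mean())
    return rbar, eps_from_rbar(n_bar, rbar)


def chronology_stats(
    raw: RingDataset,
    indices: list[IndexSeries],
    window: tuple[int, int] | None = None,
) -> ChronologyStats:
    """Summary statistics: growth rate and memory from the raw series,
    sensitivity and common signal from the residual indices."""
    lengths = np.array([len(s) for s in raw.series])
    series_means = np.array([s.values.mean() for s in raw.series])
    acs = []
    for s in raw.series:
        v = s.values
        if len(v) > 2 and v.std() > 0:
            acs.append(float(np.corrcoef(v[:-1], v[1:])[0, 1]))
    ms = [mean_sensitivity(ix.residual_index) for ix in indices]
    rbar, eps = rbar_and_eps(indices, window=window)
    return ChronologyStats(
        n_series=len(raw.series),
        length_mean=float(lengths.mean()),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        agr=float(series_means.mean()),
        agr_sd=float(series_means.std(ddof=1)) if len(series_means) > 1 else 0.0,
        rbar=rbar,
        mean_sens=float(np.mean(ms)),
        auto_corr=float(np.mean(acs)) if acs else float("nan"),
        eps=eps,
    )


# ---------------------------------------------------------------------------
# Crossdating quality control
# ---------------------------------------------------------------------------

@dataclass
class SegmentCheck:
    """One dated segment's correlation against the leave-one-out master."""

    first_year: int
    last_year: int
    r: float
    critical_r: float
    flagged: bool


def _critical_r_one_tailed(n: int, alpha: float = 0.01) -> float:
    """One-tailed critical Pearson r from the t approximation."""
    if n < 3:
        return 1.0
    t = scipy.stats.t.ppf(1.0 - alpha, n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def crossdating_check(
    series: RingSeries,
    dataset: RingDataset,
    seg_len: int = 50,
    overlap: int = 25,
    detrend_config: DetrendConfig | None = None,
) -> list[SegmentCheck]:
    """COFECHA-style dating check of one series against its peers.

    The series and every other series are spline-detrended; segments of
    ``seg_len`` years stepping by ``seg_len - overlap`` are correlated
    against the biweight master of the remaining series.  Segments with
    r below the one-tailed p < 0.01 critical value are flagged.
    """
    cfg = detrend_config or DetrendConfig(method="spline")
    others = [s for s in dataset.series if s.series_id != series.series_id]
    if not others:
        raise ValueError("crossdating needs at least one other series")

    def detrended(s: RingSeries) -> pd.Series:
        fitted = spline_fit(s.values, cfg.spline_wavelength, cfg.spline_response)
        return pd.Series(to_standard_index(s.values, fitted), index=s.years)

    target = detrended(series)
    master_frame = pd.DataFrame({s.series_id: detrended(s) for s in others})
    master = master_frame.apply(
        lambda row: biweight_mean(row.dropna().to_numpy()) if row.notna().any() else np.nan,
        axis=1,
    )

    step = max(seg_len - overlap, 1)
    starts = list(range(series.first_year, series.last_year - seg_len + 2, step))
    if not starts:
        warnings.warn(
            f"series {series.series_id!r} shorter than segment length {seg_len}; "
            "checking a single truncated segment"
        )
        starts = [series.first_year]
    checks = []
    for start in starts:
        end = min(start + seg_len - 1, series.last_year)
        yrs = np.arange(start, end + 1)
        a = target.reindex(yrs)
        b = master.reindex(yrs)
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < 3 or a[ok].std() == 0 or b[ok].std() == 0:
            checks.append(SegmentCheck(start, end, float("nan"), 1.0, True))
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        crit = _critical_r_one_tailed(n)
        checks.append(SegmentCheck(start, end, r, crit, r < crit))
    return checks


def truncate_common_period(chronology: Chronology, climate: DailyClimate) -> Chronology:
    """Clip a chronology to the calendar years fully covered by the climate record."""
    y0, y1 = climate.full_years()
    first = max(chronology.first_year, y0)
    last = min(chronology.last_year, y1)
    if first > last:
        raise ValueError(
            f"chronology ({chronology.first_year}-{chronology.last_year}) and climate "
            f"({y0}-{y1}) have no common years"
        )
    return chronology.clip(first, last)
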