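"""Bootstrapped climate–growth correlation over the daily-window grid.

For each cumulative temperature window the engine computes the Pearson
correlation between the residual chronology and the window's annual
mean temperatures, with a bootstrap over year pairs (resampled with
replacement, 1000 replicates by default).  A window is significant at
p < 0.05 when the 95% bootstrap interval excludes zero; the default
interval is BCa (bias-corrected accelerated), which holds the false
positive rate near nominal at 40-odd years of overlap, with the plain
percentile interval available as an option.  The best
window is the significant cell with the largest |r| (ties broken by
smaller width, then earlier start day).

No multiple-testing correction is applied across the ~45,000 cells:
neighbouring windows share most of their days, so the cells are
strongly dependent and the grid is read as a map, not as a family of
independent tests.

Temporal stability of a chosen window is assessed with plain Pearson
correlations in 15-year blocks stepped by one year, against the
two-tailed parametric critical value at n = 15 (|r| = 0.514).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .chronology import Chronology
from .climate_windows import SEASON_LENGTH, SeasonGrid, window_label

__all__ = [
    "BootstrapCorrelation",
    "WindowCorrelationGrid",
    "MovingCorrelation",
    "bootstrap_pearson",
    "correlate_grid",
    "moving_stability",
    "critical_r",
]


@dataclass(frozen=True)
class BootstrapCorrelation:
    """Pearson r with a percentile-bootstrap confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    significant: bool
    n_years: int
    n_boot: int
    seed: int


@dataclass
class WindowCorrelationGrid:
    """One bootstrap correlation per (start day, width) window.

    Arrays are laid out like :class:`~ringclim.climate_windows.SeasonGrid`:
    ``r[w, s]`` is the correlation for width ``widths[w]`` starting at
    season day ``s + 1``.  ``best_cell`` is ``(start_day, width)`` of
    the strongest significant correlation, or None.
    """

    widths: np.ndarray
    r: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    n_years: int
    n_boot: int
    seed: int
    best_cell: tuple[int, int] | None = field(default=None)

    def best(self) -> BootstrapCorrelation | None:
        if self.best_cell is None:
            return None
        start, width = self.best_cell
        wi = int(np.flatnonzero(self.widths == width)[0])
        s = start - 1
        return BootstrapCorrelation(
            float(self.r[wi, s]),
            float(self.ci_low[wi, s]),
            float(self.ci_high[wi, s]),
            bool(self.significant[wi, s]),
            self.n_years,
            self.n_boot,
            self.seed,
        )

    def best_label(self) -> str | None:
        if self.best_cell is None:
            return None
        start, width = self.best_cell
        lo, hi = int(self.widths[0]), int(self.widths[-1])
        return window_label(start, width, (lo, hi))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for wi, width in enumerate(self.widths):
            n_starts = SEASON_LENGTH - int(width) + 1
            for s in range(n_starts):
                if np.isfinite(self.r[wi, s]):
                    rows.append(
                        (
                            s + 1,
                            int(width),
                            self.r[wi, s],
                            self.ci_low[wi, s],
                            self.ci_high[wi, s],
                            bool(self.significant[wi, s]),
                        )
                    )
        return pd.DataFrame(
            rows, columns=["start_day", "width", "r", "ci_low", "ci_high", "significant"]
        )


@dataclass
class MovingCorrelation:
    """Pearson r in running year blocks with a parametric significance line."""

    start_years: np.ndarray
    r: np.ndarray
    significant: np.ndarray
    window_length: int
    critical_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "first_year": self.start_years,
                "last_year": self.start_years + self.window_length - 1,
                "r": self.r,
                "significant": self.significant,
            }
        )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |r| from the t distribution with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = scipy.stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _count_matrix(rng: np.random.Generator, n_boot: int, n: int) -> np.ndarray:
    """(n_boot, n) matrix of resample multiplicities, rows summing to n."""
    idx = rng.integers(0, n, size=(n_boot, n))
    offset = idx + n * np.arange(n_boot)[:, None]
    return np.bincount(offset.ravel(), minlength=n_boot * n).reshape(n_boot, n).astype(float)


def _jackknife_r(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Leave-one-out Pearson r for one x against many y rows: (n_cells, n)."""
    n = len(x)
    m = n - 1
    sx, sxx = x.sum(), (x * x).sum()
    sy = ys.sum(axis=1, keepdims=True)
    syy = (ys * ys).sum(axis=1, keepdims=True)
    sxy = (ys * x).sum(axis=1, keepdims=True)
    jsx, jsxx = sx - x, sxx - x * x  # (n,)
    jsy, jsyy, jsxy = sy - ys, syy - ys * ys, sxy - ys * x  # (n_cells, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (m * jsxy - jsx * jsy) / np.sqrt((m * jsxx - jsx**2) * (m * jsyy - jsy**2))


def _bca_bounds(
    boot: np.ndarray, r: np.ndarray, accel: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bias-corrected accelerated percentile bounds, row-wise.

    ``boot`` is (n_cells, n_boot) (NaN allowed for degenerate
    resamples), ``r`` and ``accel`` are (n_cells,).
    """
    n_cells, n_boot = boot.shape
    finite = np.isfinite(boot)
    n_valid = finite.sum(axis=1)
    frac_below = np.where(finite, boot < r[:, None], False).sum(axis=1) / np.maximum(n_valid, 1)
    frac_below = np.clip(frac_below, 1.0 / (n_valid + 1), 1.0 - 1.0 / (n_valid + 1))
    z0 = scipy.stats.norm.ppf(frac_below)
    order = np.sort(np.where(finite, boot, np.inf), axis=1)  # NaN sorted to the end

    bounds = []
    for a in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = scipy.stats.norm.ppf(a)
        adj = scipy.stats.norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))
        idx = np.clip(np.rint(adj * (n_valid - 1)).astype(int), 0, np.maximum(n_valid - 1, 0))
        bounds.append(order[np.arange(n_cells), idx])
    return bounds[0], bounds[1]


def _ci_bounds(
    boot: np.ndarray,
    r: np.ndarray,
    x: np.ndarray,
    ys: np.ndarray,
    method: str,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise bootstrap CI bounds; BCa (default) or plain percentile."""
    if method == "percentile":
        lo, hi = np.nanpercentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=1)
        return lo, hi
    if method != "bca":
        raise ValueError("ci_method must be 'bca' or 'percentile'")
    jr = _jackknife_r(x, ys)
    d = np.nanmean(jr, axis=1, keepdims=True) - jr
    num = np.nansum(d**3, axis=1)
    den = 6.0 * np.nansum(d**2, axis=1) ** 1.5
    with np.errstate(invalid="ignore", divide="ignore"):
        accel = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return _bca_bounds(boot, r, accel, alpha)


def _boot_r_from_counts(counts: np.ndarray, x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bootstrap Pearson r for one x against many y columns.

    ``counts`` is (n_boot, n); ``ys`` is (n_cells, n).  Returns
    (n_cells, n_boot).  Uses resample multiplicities so each replicate
    costs one weighted moment computation instead of a gather.
    """
    n = counts.shape[1]
    sx = counts @ x  # (n_boot,)
    sxx = counts @ (x * x)
    sy = ys @ counts.T  # (n_cells, n_boot)
    syy = (ys * ys) @ counts.T
    sxy = (ys * x) @ counts.T
    var_x = n * sxx - sx**2  # (n_boot,)
    var_y = n * syy - sy**2
    cov = n * sxy - sy * sx[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x[None, :] * var_y)
    return r


def bootstrap_pearson(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: str = "bca",
) -> BootstrapCorrelation:
    """Pearson correlation with a bootstrap CI over year pairs.

    Pairs are resampled with replacement ``n_boot`` times; the 95%
    interval gives the p < 0.05 significance decision.  The default
    interval is bias-corrected accelerated (BCa), whose coverage at the
    sample sizes of a 40-odd-year climate overlap is close to nominal;
    ``ci_method='percentile'`` selects the plain percentile interval,
    which at these sample sizes rejects a true null noticeably more
    than 5% of the time.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 paired years")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = _pearson(x, y)
    rng = np.random.default_rng(seed)
    counts = _count_matrix(rng, n_boot, n)
    boot = _boot_r_from_counts(counts, x, y[None, :])  # (1, n_boot); NaN if a resample is constant
    lo, hi = _ci_bounds(boot, np.array([r]), x, y[None, :], ci_method)
    ci_low, ci_high = float(lo[0]), float(hi[0])
    significant = bool(ci_low > 0.0 or ci_high < 0.0)
    return BootstrapCorrelation(r, ci_low, ci_high, significant, n, n_boot, seed)


def correlate_grid(
    chronology: Chronology,
    grid: SeasonGrid,
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: str = "bca",
) -> WindowCorrelationGrid:
    """Bootstrap correlation of a chronology against every climate window.

    Chronology years and grid growth years must match exactly.  The
    bootstrap stream for each width is derived deterministically from
    ``(seed, width)``, so a given master seed reproduces the grid
    bit for bit.  Cells with missing window means are left NaN.
    """
    if len(chronology.years) != len(grid.growth_years) or np.any(
        chronology.years != grid.growth_years
    ):
        raise ValueError("chronology years and grid growth years must match")
    x = np.asarray(chronology.index, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 common years")
    if x.std() == 0:
        raise ValueError("chronology has zero variance")

    n_w, max_starts, _ = grid.matrix.shape
    shape = (n_w, max_starts)
    r_arr = np.full(shape, np.nan)
    lo_arr = np.full(shape, np.nan)
    hi_arr = np.full(shape, np.nan)
    sig_arr = np.zeros(shape, dtype=bool)

    xc = x - x.mean()
    for wi, width in enumerate(grid.widths):
        n_starts = SEASON_LENGTH - int(width) + 1
        t_mat = grid.matrix[wi, :n_starts, :]  # (n_starts, n)
        complete = np.all(np.isfinite(t_mat), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tc = t_mat - np.nanmean(t_mat, axis=1, keepdims=True)
            r_row = (tc @ xc) / np.sqrt((tc**2).sum(axis=1) * (xc**2).sum())
        r_row[~complete] = np.nan
        r_arr[wi, :n_starts] = r_row

        cells = np.flatnonzero(complete & np.isfinite(r_row))
        if cells.size == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(width)]))
        counts = _count_matrix(rng, n_boot, n)
        boot = _boot_r_from_counts(counts, x, t_mat[cells])  # (n_cells, n_boot)
        lo, hi = _ci_bounds(boot, r_row[cells], x, t_mat[cells], ci_method)
        lo_arr[wi, cells] = lo
        hi_arr[wi, cells] = hi
        sig_arr[wi, cells] = (lo > 0.0) | (hi < 0.0)

    best_cell = None
    if sig_arr.any():
        absr = np.where(sig_arr, np.abs(r_arr), -np.inf)
        # argmax over |r|; ties resolved toward smaller width then earlier start
        flat = np.argwhere(absr == absr.max())
        wi, s = min(flat.tolist())
        best_cell = (int(s) + 1, int(grid.widths[wi]))
    return WindowCorrelationGrid(
        widths=grid.widths.copy(),
        r=r_arr,
        ci_low=lo_arr,
        ci_high=hi_arr,
        significant=sig_arr,
        n_years=n,
        n_boot=n_boot,
        seed=int(seed),
        best_cell=best_cell,
    )


def moving_stability(
    chronology: Chronology,
    window_series: np.ndarray,
    length: int = 15,
    step: int = 1,
    alpha: float = 0.05,
) -> MovingCorrelation:
    """Running-window Pearson correlation between chronology and one window's temperatures.

    ``window_series`` holds the annual mean temperature of a fixed
    calendar window, aligned with the chronology years.  Significance
    uses the two-tailed t critical value at the block length.
    """
    y = np.asarray(window_series, dtype=float)
    x = np.asarray(chronology.index, dtype=float)
    if len(x) != len(y):
        raise ValueError("window series must align with chronology years")
    n = len(x)
    if n < length + 1:
        raise ValueError(f"need at least {length + 1} overlapping years")
    crit = critical_r(length, alpha)
    starts = np.arange(0, n - length + 1, step)
    rs = np.array([_pearson(x[s : s + length], y[s : s + length]) for s in starts])
    return MovingCorrelation(
        start_years=chronology.years[starts],
        r=rs,
        significant=np.abs(rs) > crit,
        window_length=length,
        critical_r=crit,
    )
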