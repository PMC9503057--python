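"""Age-trend removal and autoregressive prewhitening.

Ring series mix an age/size trend (a young tree lays wide rings around
a thin stem), temporal memory, and the inter-annual climate signal the
analysis is after.  Detrending divides each raw series by a fitted
growth curve to give dimensionless *standard* indices; an AR model then
strips the remaining serial memory, giving *residual* indices.

TRW and BAI use a smoothing spline whose frequency response is 50% at a
30-year period, so variance at periods longer than a generation is
absorbed into the curve while inter-annual variance passes through.
The spline is implemented as a second-difference penalized smoother
(discrete cubic smoothing spline): for data y it solves
``(I + lam * D2'D2) s = y`` where D2 is the second-difference operator.
Its interior amplitude response is ``1 / (1 + 16*lam*sin^4(pi*f))``,
so the penalty that puts the chosen response at the chosen wavelength
has the closed form ``lam = (1/r - 1) / (16 sin^4(pi/wavelength))``.
Constants and straight lines lie in the penalty null space and are
reproduced exactly.

BI rises through the juvenile period (an artefact of the reflectance
inversion), so it is detrended with a Hugershoff growth curve
``a * t^b * exp(-c*t) + d`` fit by nonlinear least squares over cambial
ring index t = 1..n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg
from statsmodels.tsa.ar_model import AutoReg, ar_select_order

from .ring_io import RingDataset, RingSeries

__all__ = [
    "DetrendConfig",
    "IndexSeries",
    "spline_fit",
    "spline_penalty",
    "hugershoff",
    "hugershoff_fit",
    "to_standard_index",
    "ar_prewhiten",
    "detrend_series",
    "detrend_dataset",
]

#: fitted values below this fraction of the series mean are floored
#: before ratio indexing, to keep indices finite under pathological fits
FITTED_FLOOR_FRACTION = 1e-4


@dataclass(frozen=True)
class DetrendConfig:
    """Detrending choices for one proxy.

    ``spline_wavelength`` is the period (years) at which the spline's
    amplitude response equals ``spline_response`` (default: 50% at 30
    years).  ``ar_max_order`` caps the AIC search for the prewhitening
    AR model.
    """

    method: Literal["spline", "hugershoff"] = "spline"
    spline_wavelength: float = 30.0
    spline_response: float = 0.5
    ar_max_order: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("spline", "hugershoff"):
            raise ValueError("method must be 'spline' or 'hugershoff'")
        if self.spline_wavelength < 2:
            raise ValueError("spline_wavelength must be >= 2 years")
        if not 0 < self.spline_response < 1:
            raise ValueError("spline_response must lie in (0, 1)")
        if self.ar_max_order < 0:
            raise ValueError("ar_max_order must be >= 0")


@dataclass
class IndexSeries:
    """Detrended indices for one tree.

    ``standard_index`` is raw/fitted; ``residual_index`` is the
    prewhitened series, re-centred on the standard-index mean, with the
    first ``ar_order`` values set to that mean so the calendar span is
    preserved.
    """

    series_id: str
    first_year: int
    standard_index: np.ndarray
    residual_index: np.ndarray
    fitted_curve: np.ndarray
    ar_order: int = 0

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.standard_index) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)


# ---------------------------------------------------------------------------
# Smoothing spline
# ---------------------------------------------------------------------------

def spline_penalty(wavelength: float, response: float = 0.5) -> float:
    """Second-difference penalty with the given amplitude response at ``wavelength``."""
    return (1.0 / response - 1.0) / (16.0 * np.sin(np.pi / wavelength) ** 4)


def spline_fit(series: np.ndarray, wavelength: float = 30.0, response: float = 0.5) -> np.ndarray:
    """Smoothing-spline growth curve with a ``response`` frequency cutoff at ``wavelength`` years.

    Solves the penalized least-squares system for annual data; the
    result reproduces constants and straight lines exactly and passes
    half the amplitude of a 30-year oscillation at the defaults.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("spline_fit needs a 1-d series of length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    n = len(y)
    lam = spline_penalty(wavelength, response)
    d2 = scipy.sparse.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    a = scipy.sparse.eye_array(n, format="csc") + lam * (d2.T @ d2)
    return scipy.sparse.linalg.spsolve(a.tocsc(), y)


# ---------------------------------------------------------------------------
# Hugershoff curve
# ---------------------------------------------------------------------------

def hugershoff(t: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Hugershoff growth curve a * t^b * exp(-c t) + d over cambial age t."""
    return a * np.power(t, b) * np.exp(-c * t) + d


def hugershoff_fit(series: np.ndarray, return_params: bool = False):
    """Least-squares Hugershoff curve over ring index t = 1..n.

    Multi-start nonlinear least squares with a > 0 and c >= 0; on
    failure falls back to a straight-line fit, and to the series mean
    if even that is degenerate (a constant series, for instance).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 8:
        raise ValueError("hugershoff_fit needs a 1-d series of length >= 8")
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    n = len(y)
    t = np.arange(1, n + 1, dtype=float)

    if np.ptp(y) == 0.0:
        fitted, params = np.full(n, y[0]), None
        return (fitted, params) if return_params else fitted

    # log-linear seed for c: log(y - d0 + eps) ~ log a + b log t - c t
    d0 = float(y.min()) - 0.05 * float(np.ptp(y))
    with np.errstate(all="ignore"):
        z = np.log(np.maximum(y - d0, 1e-12))
        design = np.column_stack([np.ones(n), np.log(t), t])
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    c_seed = max(-float(coef[2]), 0.0)
    a_seed = max(float(np.exp(coef[0])), 1e-6)

    best, best_sse = None, np.inf
    lower = [1e-12, -5.0, 0.0, -np.inf]
    upper = [np.inf, 10.0, 5.0, np.inf]
    for b0 in (0.1, 0.5, 1.0, max(min(float(coef[1]), 9.0), -4.0)):
        p0 = [a_seed, b0, min(c_seed, 4.9), d0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = scipy.optimize.curve_fit(
                    hugershoff, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
                )
            sse = float(np.sum((hugershoff(t, *popt) - y) ** 2))
            if np.isfinite(sse) and sse < best_sse:
                best, best_sse = popt, sse
        except (RuntimeError, ValueError):
            continue

    if best is not None:
        fitted, params = hugershoff(t, *best), tuple(float(p) for p in best)
    else:
        warnings.warn("Hugershoff fit did not converge; falling back to a linear trend")
        slope, intercept = np.polyfit(t, y, 1)
        fitted = slope * t + intercept
        params = None
        if not np.all(np.isfinite(fitted)):
            fitted = np.full(n, y.mean())
    return (fitted, params) if return_params else fitted


# ---------------------------------------------------------------------------
# Ratio indices and prewhitening
# ---------------------------------------------------------------------------

def to_standard_index(raw: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """Elementwise ratio raw/fitted with a floor on tiny fitted values."""
    raw = np.asarray(raw, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if raw.shape != fitted.shape:
        raise ValueError("raw and fitted must have equal length")
    floor = FITTED_FLOOR_FRACTION * abs(float(raw.mean()))
    fitted = np.maximum(fitted, floor)
    if np.any(fitted <= 0):
        raise ValueError("fitted curve non-positive even after flooring")
    return raw / fitted


def ar_prewhiten(standard_index: np.ndarray, max_order: int = 10) -> tuple[np.ndarray, int]:
    """Remove AR(p) memory from a standard index series.

    The order p is chosen by AIC in 0..max_order.  The returned series
    has the same length: positions 0..p-1 hold the standard-index mean,
    the rest hold the AR residuals re-centred so the overall mean is
    preserved exactly.
    """
    x = np.asarray(standard_index, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("ar_prewhiten needs at least 10 values")
    if n < 30:
        warnings.warn(f"prewhitening a short series (n={n}); AR order selection is unstable")
    mean = float(x.mean())
    if np.ptp(x) == 0.0:
        warnings.warn("zero-variance series; prewhitening is a no-op")
        return x.copy(), 0
    maxlag = min(max_order, n // 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = ar_select_order(x, maxlag=maxlag, ic="aic", trend="c")
    order = 0 if not sel.ar_lags else int(max(sel.ar_lags))
    if order == 0:
        return x.copy(), 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = AutoReg(x, lags=order, trend="c").fit()
    resid = fit.resid  # length n - order
    out = np.empty(n)
    out[:order] = 0.0
    out[order:] = resid
    # re-centre so mean(residual series) == mean(standard index) exactly
    out += mean - out.mean()
    return out, order


def detrend_series(series: RingSeries, config: DetrendConfig) -> IndexSeries:
    """Raw measurements -> standard and residual index series."""
    if config.method == "spline":
        fitted = spline_fit(series.values, config.spline_wavelength, config.spline_response)
    else:
        fitted = hugershoff_fit(series.values)
    std = to_standard_index(series.values, fitted)
    resid, order = ar_prewhiten(std, config.ar_max_order)
    return IndexSeries(
        series_id=series.series_id,
        first_year=series.first_year,
        standard_index=std,
        residual_index=resid,
        fitted_curve=np.asarray(fitted),
        ar_order=order,
    )


#: the spline handles the monotone age/size trends of width and area
#: growth; the Hugershoff curve handles the juvenile rise of BI
DEFAULT_CONFIGS = {
    "TRW": DetrendConfig(method="spline"),
    "BAI": DetrendConfig(method="spline"),
    "BI": DetrendConfig(method="hugershoff"),
}


def detrend_dataset(dataset: RingDataset, config: DetrendConfig | None = None) -> list[IndexSeries]:
    """Detrend every series of a dataset with one shared configuration."""
    cfg = config or DEFAULT_CONFIGS[dataset.proxy_kind]
    return [detrend_series(s, cfg) for s in dataset.series]
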