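"""Derived tree-ring proxies: blue intensity and basal area increment.

Blue intensity (BI) inverts latewood blue reflectance (0–255) so that
denser latewood (darker, lower reflectance) yields higher values:
``BI = 2.56 - x/100``, mapping [0, 255] into (0, 2.56].

Basal area increment (BAI) converts one core's radial ring widths into
annual cross-sectional area growth.  Breast-height diameter (DBH) is
reconstructed backwards from the diameter measured in the coring year,
``DBH(t-1) = DBH(t) - 2*TRW(t)`` (radial symmetry assumed), and each
ring's area is ``BAI(t) = pi/4 * (DBH(t)^2 - DBH(t-1)^2)``.  DBH is
used as measured, over bark; cores that miss the pith simply leave the
innermost reconstructed diameter above zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ring_io import RingDataset, RingSeries, TreeRecord

__all__ = [
    "BlueReflectanceSeries",
    "BAISeries",
    "blue_intensity_transform",
    "reconstruct_dbh",
    "basal_area_increment",
    "build_bai_dataset",
    "build_bi_dataset",
]


@dataclass
class BlueReflectanceSeries:
    """Raw latewood blue reflectance (0–255), one value per year."""

    series_id: str
    first_year: int
    raw_values: np.ndarray

    def __post_init__(self) -> None:
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if self.raw_values.size == 0:
            raise ValueError(f"series {self.series_id!r}: empty reflectance series")
        if np.any(self.raw_values < 0) or np.any(self.raw_values > 255):
            raise ValueError(f"series {self.series_id!r}: reflectance must lie in [0, 255]")

    def to_blue_intensity(self) -> RingSeries:
        return RingSeries(
            self.series_id, self.first_year, blue_intensity_transform(self.raw_values), "BI"
        )


@dataclass
class BAISeries(RingSeries):
    """Annual basal area increments (mm^2) with the reconstructed DBH path.

    ``reconstructed_dbh`` holds DBH at the end of each ring year (mm),
    strictly positive and non-decreasing.
    """

    reconstructed_dbh: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proxy_kind = "BAI"
        super().__post_init__()
        if self.reconstructed_dbh is not None:
            self.reconstructed_dbh = np.asarray(self.reconstructed_dbh, dtype=float)
            if np.any(self.reconstructed_dbh <= 0):
                raise ValueError(f"series {self.series_id!r}: reconstructed DBH must be > 0")
            if np.any(np.diff(self.reconstructed_dbh) < 0):
                raise ValueError(f"series {self.series_id!r}: reconstructed DBH must be non-decreasing")
        if np.any(self.values < 0):
            raise ValueError(f"series {self.series_id!r}: BAI values must be >= 0")


def blue_intensity_transform(raw: float | np.ndarray) -> float | np.ndarray:
    """Adjusted blue intensity 2.56 - raw/100 for reflectance in [0, 255]."""
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("raw reflectance must lie in [0, 255]")
    out = 2.56 - arr / 100.0
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def reconstruct_dbh(dbh_final: float, trw: RingSeries) -> np.ndarray:
    """Back-compute DBH (mm) at the end of each ring year from the coring-year DBH.

    Returns one diameter per ring year; the last equals ``dbh_final``.
    Raises if the recursion drives any diameter to zero or below, which
    means the core is inconsistent with the measured DBH.
    """
    if not dbh_final > 0:
        raise ValueError("dbh_final must be > 0")
    increments = 2.0 * trw.values
    # DBH(t) = dbh_final - sum of doubled widths of all later rings
    later = np.concatenate([increments[::-1].cumsum()[::-1][1:], [0.0]])
    dbh = dbh_final - later
    innermost = dbh[0] - increments[0]
    if innermost <= 0 or np.any(dbh <= 0):
        raise ValueError(
            f"series {trw.series_id!r}: reconstructed DBH reaches {min(innermost, dbh.min()):.1f} mm"
            " <= 0; ring widths are inconsistent with the measured DBH"
        )
    return dbh


def basal_area_increment(dbh_now: float | np.ndarray, dbh_prev: float | np.ndarray) -> float | np.ndarray:
    """Ring area pi/4*(DBH_t^2 - DBH_{t-1}^2) in mm^2."""
    now = np.asarray(dbh_now, dtype=float)
    prev = np.asarray(dbh_prev, dtype=float)
    if np.any(prev <= 0) or np.any(now < prev):
        raise ValueError("need dbh_now >= dbh_prev > 0")
    out = np.pi / 4.0 * (now**2 - prev**2)
    return float(out) if out.ndim == 0 else out


def bai_from_trw(trw: RingSeries, dbh_final: float) -> BAISeries:
    """Full BAI series for one tree from its ring widths and final DBH."""
    dbh = reconstruct_dbh(dbh_final, trw)
    dbh_prev = dbh - 2.0 * trw.values
    return BAISeries(
        series_id=trw.series_id,
        first_year=trw.first_year,
        values=basal_area_increment(dbh, dbh_prev),
        reconstructed_dbh=dbh,
    )


def build_bai_dataset(trw_dataset: RingDataset, trees: dict[str, TreeRecord] | None = None) -> RingDataset:
    """Convert a TRW dataset to BAI, one series per tree, same year spans."""
    if trw_dataset.proxy_kind != "TRW":
        raise ValueError("BAI is derived from TRW series")
    trees = trees if trees is not None else trw_dataset.trees
    missing = [s.series_id for s in trw_dataset.series if s.series_id not in trees]
    if missing:
        raise ValueError(f"no TreeRecord (DBH) for series: {missing}")
    out = [bai_from_trw(s, trees[s.series_id].dbh_final) for s in trw_dataset.series]
    return RingDataset(series=out, trees=dict(trees), proxy_kind="BAI")


def build_bi_dataset(
    reflectance: list[BlueReflectanceSeries], trees: dict[str, TreeRecord] | None = None
) -> RingDataset:
    """Transform raw reflectance series into a blue-intensity dataset."""
    return RingDataset(
        series=[r.to_blue_intensity() for r in reflectance],
        trees=dict(trees) if trees else {},
        proxy_kind="BI",
    )
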