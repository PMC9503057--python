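"""Reading and writing the file formats of the ring–climate pipeline.

Ring-width series travel as Tucson/RWL decadal files (the community
standard), blue-intensity and basal-area series as long-format CSV
(``series_id, year, value``), per-tree metadata and daily temperatures
as plain CSV.  All series are anchored to calendar years of ring
formation; alignment throughout the package is by calendar year.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "TreeRecord",
    "RingDataset",
    "DailyClimate",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_series_csv",
    "write_series_csv",
    "read_trees_csv",
    "write_trees_csv",
    "read_reflectance_csv",
    "write_reflectance_csv",
    "read_daily_climate",
    "write_daily_climate",
]

ProxyKind = Literal["TRW", "BAI", "BI"]

#: Tucson sentinel -> measurement unit in mm.  A decade row terminated by
#: -9999 encodes values in 0.001 mm; one terminated by 999 encodes 0.01 mm.
_SENTINEL_UNITS = {-9999: 0.001, 999: 0.01}


class RwlParseError(ValueError):
    """Raised when a Tucson/RWL file cannot be interpreted."""


@dataclass
class RingSeries:
    """One tree's annual measurements anchored to calendar years.

    Values are mm for TRW, mm^2 for BAI and unitless (0, 2.56] for BI.
    There is exactly one value per consecutive calendar year.
    """

    series_id: str
    first_year: int
    values: np.ndarray
    proxy_kind: ProxyKind = "TRW"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"series {self.series_id!r}: values must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.series_id!r}: values must be finite (no gaps allowed)")
        if self.proxy_kind == "TRW" and np.any(self.values < 0):
            raise ValueError(f"series {self.series_id!r}: TRW values must be >= 0")
        if self.proxy_kind == "BI" and (np.any(self.values <= 0) or np.any(self.values > 2.56)):
            raise ValueError(f"series {self.series_id!r}: BI values must lie in (0, 2.56]")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingSeries):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.first_year == other.first_year
            and self.proxy_kind == other.proxy_kind
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class TreeRecord:
    """Per-tree metadata: final breast-height diameter and site group.

    ``dbh_final`` is the mean of two perpendicular breast-height
    diameters, in mm, measured in the year of coring.
    """

    series_id: str
    dbh_final: float
    elevation_class: Literal["low", "high"] = "low"

    def __post_init__(self) -> None:
        if not self.dbh_final > 0:
            raise ValueError(f"tree {self.series_id!r}: dbh_final must be > 0")
        if self.elevation_class not in ("low", "high"):
            raise ValueError(f"tree {self.series_id!r}: elevation_class must be 'low' or 'high'")


@dataclass
class RingDataset:
    """A collection of same-proxy ring series plus per-tree metadata."""

    series: list[RingSeries]
    trees: dict[str, TreeRecord] = field(default_factory=dict)
    proxy_kind: ProxyKind = "TRW"

    def __post_init__(self) -> None:
        ids = [s.series_id for s in self.series]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate series ids: {sorted(dupes)}")
        for s in self.series:
            if s.proxy_kind != self.proxy_kind:
                raise ValueError(
                    f"series {s.series_id!r} has proxy {s.proxy_kind}, dataset is {self.proxy_kind}"
                )

    @property
    def span(self) -> tuple[int, int]:
        if not self.series:
            raise ValueError("empty dataset has no span")
        return (min(s.first_year for s in self.series), max(s.last_year for s in self.series))

    def get(self, series_id: str) -> RingSeries:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)

    def subset(self, ids: Iterable[str]) -> "RingDataset":
        ids = set(ids)
        return RingDataset(
            series=[s for s in self.series if s.series_id in ids],
            trees={k: v for k, v in self.trees.items() if k in ids},
            proxy_kind=self.proxy_kind,
        )

    def by_elevation(self, elevation_class: str) -> "RingDataset":
        ids = [k for k, t in self.trees.items() if t.elevation_class == elevation_class]
        return self.subset(ids)

    def __len__(self) -> int:
        return len(self.series)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingDataset):
            return NotImplemented
        return (
            self.proxy_kind == other.proxy_kind
            and self.trees == other.trees
            and self.series == other.series
        )


@dataclass
class DailyClimate:
    """Calendar-dated daily mean temperatures from one station.

    ``dates`` is strictly increasing; calendar days missing between the
    first and last record are listed in ``gaps``.
    """

    station_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    gaps: pd.DatetimeIndex = field(default_factory=lambda: pd.DatetimeIndex([]))

    def __post_init__(self) -> None:
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise ValueError("dates and tmean must have equal length")
        if len(self.dates) and not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if len(self.dates) and self.dates.has_duplicates:
            raise ValueError("duplicate dates")
        if not np.all(np.isfinite(self.tmean)):
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return len(self.dates)

    def as_series(self) -> pd.Series:
        """Daily temperatures on a complete calendar grid, NaN at gaps."""
        s = pd.Series(self.tmean, index=self.dates)
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        return s.reindex(full)

    def full_years(self) -> tuple[int, int]:
        """First and last calendar year fully covered by the record."""
        first, last = self.dates[0], self.dates[-1]
        y0 = first.year if (first.month, first.day) == (1, 1) else first.year + 1
        y1 = last.year if (last.month, last.day) == (12, 31) else last.year - 1
        if y1 < y0:
            raise ValueError("climate record covers no complete calendar year")
        return y0, y1


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

def read_rwl(path: str | Path, proxy_kind: ProxyKind = "TRW") -> RingDataset:
    """Read a Tucson/RWL decadal file into a :class:`RingDataset`.

    The measurement unit is detected per series from the terminal
    sentinel: -9999 means 0.001 mm, 999 means 0.01 mm.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise RwlParseError(f"{path.name}:{lineno}: malformed decade line")
            try:
                year = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise RwlParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from None
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            raw[sid].append((year, vals))

    series = []
    for sid in order:
        blocks = sorted(raw[sid], key=lambda b: b[0])
        flat: list[int] = []
        first_year = blocks[0][0]
        expect = first_year
        for year, vals in blocks:
            if year != expect:
                raise RwlParseError(
                    f"series {sid!r}: decade starting {year} does not follow year {expect - 1}"
                )
            flat.extend(vals)
            expect = year + len(vals)
        if not flat or flat[-1] not in _SENTINEL_UNITS:
            raise RwlParseError(f"series {sid!r}: missing terminal sentinel (-9999 or 999)")
        unit = _SENTINEL_UNITS[flat[-1]]
        values = np.array(flat[:-1], dtype=float) * unit
        series.append(RingSeries(sid, first_year, values, proxy_kind=proxy_kind))
    return RingDataset(series=series, proxy_kind=proxy_kind)


def write_rwl(dataset: RingDataset, path: str | Path, precision: float = 0.001) -> Path:
    """Write a TRW dataset as a Tucson/RWL decadal file.

    ``precision`` selects the dialect: 0.001 mm (sentinel -9999, the
    default) or 0.01 mm (sentinel 999).
    """
    if dataset.proxy_kind != "TRW":
        raise ValueError(
            f"RWL export holds integer ring widths only; write {dataset.proxy_kind} "
            "series as long-format CSV (write_series_csv) instead"
        )
    if not dataset.series:
        raise ValueError("refusing to write an empty dataset")
    sentinel = {0.001: -9999, 0.01: 999}.get(precision)
    if sentinel is None:
        raise ValueError("precision must be 0.001 or 0.01 (mm)")
    for s in dataset.series:
        if len(s.series_id) > 8:
            raise ValueError(f"series id {s.series_id!r} exceeds 8 characters")

    path = Path(path)
    with open(path, "w") as fh:
        for s in dataset.series:
            ints = np.rint(s.values / precision).astype(int)
            year = s.first_year
            pos = 0
            while pos < len(ints):
                decade_end = (year // 10) * 10 + 9
                take = min(decade_end - year + 1, len(ints) - pos)
                row = ints[pos : pos + take].tolist()
                pos += take
                # sentinel occupies the next value slot; a series ending on a
                # decade boundary carries it on its own continuation line
                if pos == len(ints) and year + take <= decade_end:
                    row.append(sentinel)
                fh.write(f"{s.series_id:<8}{year:4d}" + "".join(f"{v:6d}" for v in row) + "\n")
                year += take
            if year % 10 == 0:
                fh.write(f"{s.series_id:<8}{year:4d}{sentinel:6d}\n")
    return path


# ---------------------------------------------------------------------------
# Long-format CSV (BI / BAI / index series)
# ---------------------------------------------------------------------------

def write_series_csv(dataset: RingDataset, path: str | Path) -> Path:
    """Write any ring dataset as long-format CSV (series_id, year, value)."""
    path = Path(path)
    rows = [
        {"series_id": s.series_id, "year": y, "value": v}
        for s in dataset.series
        for y, v in zip(s.years, s.values)
    ]
    pd.DataFrame(rows, columns=["series_id", "year", "value"]).to_csv(path, index=False)
    return path


def read_series_csv(path: str | Path, proxy_kind: ProxyKind) -> RingDataset:
    """Read a long-format CSV (series_id, year, value) ring dataset."""
    df = pd.read_csv(path, dtype={"series_id": str})
    missing = {"series_id", "year", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if np.any(np.diff(years) != 1):
            raise ValueError(f"series {sid!r}: years are not consecutive")
        series.append(RingSeries(str(sid), int(years[0]), grp["value"].to_numpy(), proxy_kind))
    return RingDataset(series=series, proxy_kind=proxy_kind)


def write_reflectance_csv(series: Sequence, path: str | Path) -> Path:
    """Write raw blue-reflectance series (0-255) as long-format CSV."""
    rows = [
        {"series_id": s.series_id, "year": s.first_year + i, "value": v}
        for s in series
        for i, v in enumerate(s.raw_values)
    ]
    pd.DataFrame(rows, columns=["series_id", "year", "value"]).to_csv(path, index=False)
    return Path(path)


def read_reflectance_csv(path: str | Path) -> list:
    """Read raw blue-reflectance series from long-format CSV."""
    from .proxies import BlueReflectanceSeries

    df = pd.read_csv(path, dtype={"series_id": str})
    missing = {"series_id", "year", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if np.any(np.diff(years) != 1):
            raise ValueError(f"series {sid!r}: years are not consecutive")
        out.append(BlueReflectanceSeries(str(sid), int(years[0]), grp["value"].to_numpy()))
    return out


def write_trees_csv(trees: dict[str, TreeRecord] | Sequence[TreeRecord], path: str | Path) -> Path:
    recs = trees.values() if isinstance(trees, dict) else trees
    pd.DataFrame([dataclasses.asdict(t) for t in recs]).to_csv(path, index=False)
    return Path(path)


def read_trees_csv(path: str | Path) -> dict[str, TreeRecord]:
    df = pd.read_csv(path, dtype={"series_id": str})
    missing = {"series_id", "dbh_final", "elevation_class"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(r.series_id): TreeRecord(str(r.series_id), float(r.dbh_final), str(r.elevation_class))
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Daily climate CSV
# ---------------------------------------------------------------------------

def read_daily_climate(
    path: str | Path,
    station_id: str | None = None,
    date_col: str = "date",
    temp_col: str = "tmean",
) -> DailyClimate:
    """Read a daily mean-temperature table (ISO-8601 dates).

    Missing calendar days between the first and last record are
    recorded in the ``gaps`` attribute; downstream window aggregation
    decides whether a gap is tolerable.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (date_col, temp_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    try:
        dates = pd.to_datetime(df[date_col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date ({exc})") from None
    temps = pd.to_numeric(df[temp_col], errors="coerce").to_numpy()
    if np.any(~np.isfinite(temps)):
        bad = int(np.flatnonzero(~np.isfinite(temps))[0])
        raise ValueError(f"{path}: non-numeric temperature at row {bad + 2} (date {df[date_col].iloc[bad]})")
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValueError(f"{path}: dates must be strictly increasing")
    idx = pd.DatetimeIndex(dates)
    full = pd.date_range(idx[0], idx[-1], freq="D")
    gaps = full.difference(idx)
    return DailyClimate(station_id or path.stem, idx, temps, gaps)


def write_daily_climate(climate: DailyClimate, path: str | Path) -> Path:
    pd.DataFrame(
        {"date": climate.dates.strftime("%Y-%m-%d"), "tmean": climate.tmean}
    ).to_csv(path, index=False)
    return Path(path)
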