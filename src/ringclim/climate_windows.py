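"""Cumulative daily temperature windows across the dendro growth year.

The temperature signal in a ring need not respect calendar months, so
daily means are aggregated over *every* window of 21–120 consecutive
days inside the growth season, which runs from June 1 of the previous
year through October 31 of the current year.  With February 29 dropped,
that season is always 518 days long: 214 previous-year days
(Jun 1 – Dec 31) plus 304 current-year days (Jan 1 – Oct 31).

The result is a grid ``(width, start day, growth year) -> mean
temperature`` over which the correlation engine sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ring_io import DailyClimate

__all__ = [
    "SEASON_LENGTH",
    "SEASON_DAYS",
    "PREV_YEAR_DAYS",
    "SeasonGrid",
    "build_season_grid",
    "window_label",
    "season_day_of",
]

#: (month, day) for each season day, June 1 (previous year) .. Oct 31
#: (current year); no Feb 29 entry.
_MONTH_LEN = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30, 7: 31, 8: 31, 9: 30, 10: 31, 11: 30, 12: 31}


def _build_axis() -> list[tuple[int, int, bool]]:
    axis = []
    for month in range(6, 13):  # previous year: June .. December
        axis.extend((month, day, True) for day in range(1, _MONTH_LEN[month] + 1))
    for month in range(1, 11):  # current year: January .. October
        axis.extend((month, day, False) for day in range(1, _MONTH_LEN[month] + 1))
    return axis


SEASON_DAYS = _build_axis()
SEASON_LENGTH = len(SEASON_DAYS)  # 518
PREV_YEAR_DAYS = sum(_MONTH_LEN[m] for m in range(6, 13))  # 214

_MONTH_ABBR = ["", "Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def season_day_of(month: int, day: int, previous_year: bool) -> int:
    """1-based season index of a calendar day (Feb 29 maps to Feb 28)."""
    if month == 2 and day == 29:
        day = 28
    try:
        return SEASON_DAYS.index((month, day, previous_year)) + 1
    except ValueError:
        raise ValueError(
            f"({month}, {day}, previous={previous_year}) is outside the Jun-1(prev) .. Oct-31 season"
        ) from None


@dataclass
class SeasonGrid:
    """Window-mean temperatures for every (start day, width) and growth year.

    ``matrix[w, s, y]`` is the mean temperature of the window of width
    ``widths[w]`` starting at season day ``s + 1`` in growth year
    ``growth_years[y]``; NaN where the window would run past October 31
    or has too many missing days.
    """

    growth_years: np.ndarray
    widths: np.ndarray
    matrix: np.ndarray  # (n_widths, max_starts, n_years)
    station_id: str = ""

    @property
    def n_starts(self) -> np.ndarray:
        """Number of admissible start days per width."""
        return SEASON_LENGTH - self.widths + 1

    def window_series(self, start_day: int, width: int) -> np.ndarray:
        """Annual mean temperatures of one fixed window across growth years."""
        w = int(np.flatnonzero(self.widths == width)[0]) if width in self.widths else None
        if w is None:
            raise ValueError(f"width {width} not in grid")
        if not 1 <= start_day <= SEASON_LENGTH - width + 1:
            raise ValueError(f"start day {start_day} out of range for width {width}")
        return self.matrix[w, start_day - 1, :]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: growth_year, start_day, width, mean_temp."""
        rows = []
        for wi, width in enumerate(self.widths):
            for s in range(SEASON_LENGTH - width + 1):
                col = self.matrix[wi, s, :]
                for yi, year in enumerate(self.growth_years):
                    if np.isfinite(col[yi]):
                        rows.append((int(year), s + 1, int(width), col[yi]))
        return pd.DataFrame(rows, columns=["growth_year", "start_day", "width", "mean_temp"])


def _season_daily_matrix(climate: DailyClimate, years: np.ndarray) -> np.ndarray:
    """(n_years, 518) daily temperatures, NaN at gaps, Feb 29 dropped."""
    s = climate.as_series()
    is_feb29 = (s.index.month == 2) & (s.index.day == 29)
    s = s[~is_feb29]
    out = np.full((len(years), SEASON_LENGTH), np.nan)
    for yi, y in enumerate(years):
        start = pd.Timestamp(int(y) - 1, 6, 1)
        end = pd.Timestamp(int(y), 10, 31)
        chunk = s.loc[(s.index >= start) & (s.index <= end)]
        if len(chunk) == SEASON_LENGTH:
            out[yi] = chunk.to_numpy()
        else:
            # partially covered season: align day by day
            for ts, val in chunk.items():
                prev = ts.year == y - 1
                out[yi, season_day_of(ts.month, ts.day, prev) - 1] = val
    return out


def build_season_grid(
    climate: DailyClimate,
    years: np.ndarray | list[int],
    widths: tuple[int, int] = (21, 120),
    min_coverage: float = 0.95,
) -> SeasonGrid:
    """Aggregate daily temperatures into all cumulative windows.

    A window's mean is computed over its present days when at least
    ``min_coverage`` of them are present, else the cell is NaN.  A
    growth year with no data at all raises.
    """
    years = np.asarray(years, dtype=int)
    w_arr = np.arange(widths[0], widths[1] + 1)
    if widths[0] < 1 or widths[1] > SEASON_LENGTH or widths[0] > widths[1]:
        raise ValueError(f"widths must satisfy 1 <= lo <= hi <= {SEASON_LENGTH}")
    daily = _season_daily_matrix(climate, years)
    empty = ~np.isfinite(daily).any(axis=1)
    if empty.any():
        raise ValueError(f"no climate data at all for growth years {years[empty].tolist()}")

    n_years = len(years)
    max_starts = SEASON_LENGTH - w_arr[0] + 1
    matrix = np.full((len(w_arr), max_starts, n_years), np.nan)

    filled = np.nan_to_num(daily, nan=0.0)
    csum = np.concatenate([np.zeros((n_years, 1)), np.cumsum(filled, axis=1)], axis=1)
    ccnt = np.concatenate(
        [np.zeros((n_years, 1), dtype=int), np.cumsum(np.isfinite(daily), axis=1)], axis=1
    )
    for wi, w in enumerate(w_arr):
        n_starts = SEASON_LENGTH - w + 1
        sums = csum[:, w:] - csum[:, :-w]  # (n_years, n_starts)
        cnts = ccnt[:, w:] - ccnt[:, :-w]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cnts >= min_coverage * w, sums / np.maximum(cnts, 1), np.nan)
        matrix[wi, :n_starts, :] = means.T
    return SeasonGrid(years, w_arr, matrix, station_id=climate.station_id)


def window_label(start_day: int, width: int, widths: tuple[int, int] = (21, 120)) -> str:
    """Calendar label for a window, lowercase for the previous year.

    Examples: ``"jun 1 – jun 21 (previous year)"``, ``"Aug 15 – Oct 12"``,
    ``"dec 3 – Jan 18"`` for a window crossing the year boundary.
    """
    if not widths[0] <= width <= widths[1]:
        raise ValueError(f"width {width} outside [{widths[0]}, {widths[1]}]")
    end_day = start_day + width - 1
    if not (1 <= start_day <= SEASON_LENGTH and end_day <= SEASON_LENGTH):
        raise ValueError(f"window ({start_day}, width {width}) runs outside the season axis")

    def fmt(idx: int) -> tuple[str, bool]:
        month, day, prev = SEASON_DAYS[idx - 1]
        name = _MONTH_ABBR[month]
        return (f"{name.lower()} {day}" if prev else f"{name} {day}"), prev

    a, prev_a = fmt(start_day)
    b, prev_b = fmt(end_day)
    label = f"{a} – {b}"
    if prev_a and prev_b:
        label += " (previous year)"
    return label
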