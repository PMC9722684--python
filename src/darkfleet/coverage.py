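"""Plan satellite coverage of fishing activity.

Activity hours are gridded into 4°×4° cells (roughly one radar image) by
52 calendar weeks; cells are then taken greedily in decreasing-activity
order until a target fraction of the total is covered. For this separable
objective the greedy pick is exactly the minimum-cardinality selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_DEG = 4.0
N_WEEKS = 52


def cell_index(lat, lon):
    """Half-open 4° cell indices: lat bands [−90, 90), lon [−180, 180)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    ilat = np.floor((lat + 90.0) / CELL_DEG).astype(int)
    ilon = np.floor((lon + 180.0) / CELL_DEG).astype(int)
    return ilat, ilon


def week_index(timestamps: pd.Series, year: int) -> np.ndarray:
    """52-week partition of the calendar year: 7-day blocks from Jan 1,
    with the last days of the year folded into week 52."""
    doy = pd.DatetimeIndex(timestamps).dayofyear.to_numpy()
    return np.minimum((doy - 1) // 7, N_WEEKS - 1)


@dataclass
class EffortGrid:
    cells: dict = field(default_factory=dict)  # (ilat, ilon, week) -> hours
    year: int = 2020
    n_rejected: int = 0

    @property
    def total_hours(self) -> float:
        return float(sum(self.cells.values()))

    @property
    def n_occupied(self) -> int:
        return sum(1 for v in self.cells.values() if v > 0)


def grid_effort(records: pd.DataFrame, year: int | None = None) -> EffortGrid:
    """Accumulate effort records (lat, lon, timestamp, hours) into
    cell-week bins; hours are conserved. Records outside the calendar
    year are rejected and counted."""
    ts = pd.to_datetime(records["timestamp"], utc=True)
    if year is None:
        year = int(ts.dt.year.mode().iloc[0])
    in_year = (ts.dt.year == year).to_numpy()
    kept = records.loc[in_year]
    ilat, ilon = cell_index(kept["lat"].to_numpy(), kept["lon"].to_numpy())
    week = week_index(ts[in_year], year)
    grid = EffortGrid(year=year, n_rejected=int((~in_year).sum()))
    for a, o, w, h in zip(ilat, ilon, week, kept["hours"].to_numpy()):
        k = (int(a), int(o), int(w))
        grid.cells[k] = grid.cells.get(k, 0.0) + float(h)
    return grid


@dataclass
class CoveragePlan:
    scenes_needed: int
    target_fraction: float
    covered_fraction: float
    schedule: pd.DataFrame       # week, lat0, lon0, hours, cumulative_fraction
    n_occupied_cells: int
    n_total_cells: int           # full ocean grid × weeks


def greedy_cover(grid: EffortGrid, target_fraction: float) -> CoveragePlan:
    """Cells sorted by hours descending (ties broken by cell index) are
    accumulated until the target fraction of total activity is covered;
    one scene images one cell-week."""
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    total = grid.total_hours
    if total <= 0:
        raise ValueError("grid has no activity")
    items = sorted(grid.cells.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = []
    cum = 0.0
    for (ilat, ilon, week), hours in items:
        if cum >= target_fraction * total:
            break
        cum += hours
        rows.append(
            {
                "week": week + 1,
                "lat0": ilat * CELL_DEG - 90.0,
                "lon0": ilon * CELL_DEG - 180.0,
                "hours": hours,
                "cumulative_fraction": cum / total,
            }
        )
    schedule = pd.DataFrame(rows, columns=["week", "lat0", "lon0", "hours", "cumulative_fraction"])
    n_total = int((180 // CELL_DEG) * (360 // CELL_DEG) * N_WEEKS)
    return CoveragePlan(
        scenes_needed=len(rows),
        target_fraction=target_fraction,
        covered_fraction=(rows[-1]["cumulative_fraction"] if rows else 0.0),
        schedule=schedule,
        n_occupied_cells=grid.n_occupied,
        n_total_cells=n_total,
    )
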