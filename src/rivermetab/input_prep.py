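"""Assembly of per-site model-input tables.

Non-oxygen variables are linearly interpolated onto the O2 timestamps; data
gaps of at most 3 h are filled, while any metabolism day whose 24-h window
(04:00-03:59 mean solar) overlaps a longer gap in any variable is excluded.
Days containing nonpositive flow (intermittent or tidal) and edge days with
incomplete windows are likewise excluded.  O2 series whose sampling
resolution changes over the record are split into uniform-resolution chunks,
one model application per chunk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcings import (CFS_TO_CMS, convert_UTC_to_solartime, derive_forcings,
                       metabolism_dates)
from .timeseries import SiteRecord, TimeSeries

#: maximum gap (hours) that may be filled by interpolation
MAX_GAP_HOURS = 3.0

REASONS = ("none", "gap>3h", "nonpositive_flow", "incomplete_window")


@dataclass
class DayValidity:
    date: object  # datetime.date
    valid: bool
    reason: str = "none"

    def __post_init__(self):
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")


@dataclass
class ModelInput:
    """Merged per-site model input on a uniform timestep grid.

    ``table`` is indexed by UTC timestamps with columns sitetime (mean solar,
    tz-naive), date (metabolism date), doobs, dosat, depth, wtr, ppfd,
    discharge (m^3 s^-1).  All candidate dates appear in ``validity`` exactly
    once; rows for invalid days are retained in the table but excluded from
    fitting.
    """

    table: pd.DataFrame
    resolution_min: float
    validity: list[DayValidity]

    @property
    def valid_dates(self) -> list:
        return [v.date for v in self.validity if v.valid]

    def day_rows(self, date) -> pd.DataFrame:
        return self.table[self.table["date"] == date]

    def messages(self) -> pd.DataFrame:
        """One row per candidate date with its exclusion reason (if any)."""
        return pd.DataFrame(
            [{"date": v.date, "valid": v.valid,
              "message": "" if v.valid else f"excluded: {v.reason}"}
             for v in self.validity]
        )


def _gap_intervals(idx: pd.DatetimeIndex, max_gap_h: float = MAX_GAP_HOURS):
    """(start, end) UTC pairs of within-span gaps strictly longer than max_gap_h."""
    if len(idx) < 2:
        return []
    dt_h = np.diff(idx.asi8) / 3.6e12
    out = []
    for i in np.nonzero(dt_h > max_gap_h)[0]:
        out.append((idx[i], idx[i + 1]))
    return out


def split_by_resolution(o2: TimeSeries, persist_points: int = 4) -> list[TimeSeries]:
    """Split an O2 series into chunks of uniform nominal resolution.

    A change in timestep defines a new chunk only when the new spacing
    persists for at least ``persist_points`` consecutive steps; shorter
    excursions (isolated missing or jittered timestamps) stay within the
    current chunk.
    """
    idx = o2.timestamps
    if len(idx) < 2:
        return [o2]
    dts = np.round(np.diff(idx.asi8) / 60e9, 1)  # minutes
    res = dts[0]
    boundaries = [0]
    resolutions = [res]
    i = 0
    n = len(dts)
    while i < n:
        if dts[i] != res and i + persist_points <= n and \
                np.all(dts[i:i + persist_points] == dts[i]):
            boundaries.append(i)
            res = dts[i]
            resolutions.append(res)
            i += persist_points
        else:
            i += 1
    boundaries.append(len(idx))
    chunks = []
    for k in range(len(boundaries) - 1):
        lo, hi = boundaries[k], boundaries[k + 1]
        sub = o2.series.iloc[lo:hi]
        chunks.append(TimeSeries(o2.variable, sub, float(resolutions[k]), o2.units))
    return chunks


def merge_and_interpolate(o2: TimeSeries, others: dict[str, TimeSeries],
                          longitude: float,
                          max_gap_h: float = MAX_GAP_HOURS) -> ModelInput:
    """Merge forcing series onto the O2 timestamps and classify days.

    ``others`` must provide dosat, depth, wtr, ppfd, discharge, each as a
    TimeSeries overlapping the O2 span.  The O2 series must have a single
    nominal resolution (see :func:`split_by_resolution`).
    """
    required = {"dosat", "depth", "wtr", "ppfd", "discharge"}
    missing = required - set(others)
    if missing:
        raise KeyError(f"missing model-input variables: {sorted(missing)}")

    res_min = o2.resolution_min
    step = pd.Timedelta(minutes=res_min)
    grid = pd.date_range(o2.timestamps[0], o2.timestamps[-1], freq=step)

    # O2 onto the full grid; gaps (of any length) linearly interpolated --
    # long gaps are handled by day-level exclusion below
    doobs = o2.series.reindex(grid)
    doobs = doobs.interpolate(method="time", limit_direction="both")

    data = {"doobs": doobs.to_numpy()}
    gap_by_var = {"doobs": _gap_intervals(o2.timestamps, max_gap_h)}
    gx = grid.asi8.astype(float)
    for name, ts in others.items():
        vals = np.interp(gx, ts.timestamps.asi8.astype(float), ts.values)
        data[name] = vals
        gaps = _gap_intervals(ts.timestamps, max_gap_h)
        # regions outside the variable's span count as missing data
        if ts.timestamps[0] > grid[0]:
            gaps.append((grid[0] - step, ts.timestamps[0]))
        if ts.timestamps[-1] < grid[-1]:
            gaps.append((ts.timestamps[-1], grid[-1] + step))
        gap_by_var[name] = gaps

    table = pd.DataFrame(data, index=grid)
    table["sitetime"] = convert_UTC_to_solartime(grid, longitude, "mean")
    table["date"] = metabolism_dates(grid, longitude)

    rows_per_day = int(round(1440.0 / res_min))
    validity: list[DayValidity] = []
    for date, day in table.groupby("date", sort=True):
        if len(day) < rows_per_day:
            validity.append(DayValidity(date, False, "incomplete_window"))
            continue
        w_start = day.index[0]
        w_end = day.index[-1] + step
        has_gap = any(
            g_start < w_end and g_end > w_start
            for gaps in gap_by_var.values() for (g_start, g_end) in gaps
        )
        if has_gap:
            validity.append(DayValidity(date, False, "gap>3h"))
        else:
            validity.append(DayValidity(date, True))

    cols = ["sitetime", "date", "doobs", "dosat", "depth", "wtr", "ppfd", "discharge"]
    return ModelInput(table[cols], float(res_min), validity)


def filter_positive_flow(mi: ModelInput) -> ModelInput:
    """Invalidate any day containing nonpositive discharge (in place).

    Only days with entirely positive flow are modeled, avoiding intermittent
    flow and tidal reversal.
    """
    for v in mi.validity:
        if not v.valid:
            continue
        q = mi.day_rows(v.date)["discharge"].to_numpy()
        if np.any(~np.isfinite(q)) or np.any(q <= 0):
            v.valid = False
            v.reason = "nonpositive_flow"
    return mi


def prepare_model_input(site: SiteRecord, raws: dict[str, TimeSeries],
                        max_gap_h: float = MAX_GAP_HOURS) -> list[ModelInput]:
    """Full preparation: derive forcings, split O2 by resolution, merge, filter.

    Returns one ModelInput per uniform-resolution chunk of the O2 record.
    """
    derived = derive_forcings(site, raws)
    disch = raws["disch_nwis"]
    disch_cms = TimeSeries(
        "disch_cms", pd.Series(disch.values * CFS_TO_CMS, index=disch.timestamps),
        disch.resolution_min)
    out = []
    for o2_chunk in split_by_resolution(raws["doobs_nwis"]):
        span = (o2_chunk.timestamps[0], o2_chunk.timestamps[-1] + pd.Timedelta(minutes=1))
        others = {
            "dosat": derived["dosat_calcGGbts"],
            "depth": derived["depth_calcDischHarvey"],
            "wtr": raws["wtr_nwis"],
            "ppfd": derived["par_calcLatSw"].slice(*span),
            "discharge": disch_cms,
        }
        mi = merge_and_interpolate(o2_chunk, others, site.longitude, max_gap_h)
        out.append(filter_positive_flow(mi))
    return out
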