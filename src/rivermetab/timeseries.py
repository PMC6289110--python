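"""Core containers: site metadata and single-variable sensor time series.

The pipeline mirrors the layout of multi-site sensor archives: one file (or
in-memory :class:`TimeSeries`) per site-variable combination, plus a static
:class:`SiteRecord` holding coordinates and hydraulic-geometry coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: canonical units per variable name (raw and derived vocabulary)
VARIABLE_UNITS: dict[str, str] = {
    "doobs_nwis": "mg O2 L^-1",
    "wtr_nwis": "degC",
    "disch_nwis": "ft^3 s^-1",
    "baro_nldas": "Pa",
    "baro_gldas": "Pa",
    "sw_nldas": "W m^-2",
    "sw_gldas": "W m^-2",
    "baro_calcElev": "Pa",
    "depth_calcDischHarvey": "m",
    "depth_calcDischRaymond": "m",
    "veloc_calcDischHarvey": "m s^-1",
    "veloc_calcDischRaymond": "m s^-1",
    "dosat_calcGGbts": "mg O2 L^-1",
    "dosat_calcGGbconst": "mg O2 L^-1",
    "dopsat_calcObsSat": "%",
    "par_calcLat": "umol m^-2 s^-1",
    "par_calcSw": "umol m^-2 s^-1",
    "par_calcLatSw": "umol m^-2 s^-1",
    "sitetime_calcLon": "",
    "suntime_calcLat": "",
}


@dataclass(frozen=True)
class SiteRecord:
    """Static site metadata.

    ``depth_coefs = (c, f)`` and ``veloc_coefs = (k, m)`` are at-a-station
    hydraulic-geometry power-law coefficients: depth = c * Q**f (m) and
    velocity = k * Q**m (m s^-1) with Q in m^3 s^-1.
    ``structure_distances`` maps structure type (``canal``, ``dam``,
    ``npdes``) to the distance (m) to the nearest upstream structure.
    """

    site_id: str
    latitude: float
    longitude: float
    altitude: float
    depth_coefs: tuple[float, float]
    veloc_coefs: tuple[float, float]
    structure_distances: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.depth_coefs[0] <= 0:
            raise ValueError("depth coefficient c must be > 0")
        if self.veloc_coefs[0] <= 0:
            raise ValueError("velocity coefficient k must be > 0")


@dataclass
class TimeSeries:
    """One variable's timestamped values.

    ``series`` is a pandas Series indexed by a tz-aware UTC DatetimeIndex,
    strictly increasing with no duplicates.  ``resolution_min`` is the
    nominal sampling step; if None it is inferred as the median step.
    """

    variable: str
    series: pd.Series
    resolution_min: float | None = None
    units: str = field(default="")

    def __post_init__(self) -> None:
        idx = self.series.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("TimeSeries requires a DatetimeIndex")
        if idx.tz is None:
            raise ValueError("timestamps must be tz-aware (UTC)")
        if len(idx) > 1:
            dt = np.diff(idx.asi8)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.resolution_min is None and len(idx) > 1:
            self.resolution_min = float(
                np.median(np.diff(idx.asi8)) / 60e9
            )
        if not self.units:
            self.units = VARIABLE_UNITS.get(self.variable, "")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.series.index

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy(dtype=float)

    def slice(self, start, end) -> "TimeSeries":
        """Return the subseries with start <= t < end."""
        sub = self.series[(self.series.index >= start) & (self.series.index < end)]
        return TimeSeries(self.variable, sub, self.resolution_min, self.units)


def make_timeseries(variable: str, timestamps, values, resolution_min=None) -> TimeSeries:
    """Build a TimeSeries from timestamp-like and value arrays."""
    idx = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True))
    return TimeSeries(variable, pd.Series(np.asarray(values, dtype=float), index=idx),
                      resolution_min)
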