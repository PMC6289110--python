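"""Derived forcing variables for metabolism modeling.

Starting from five raw series per site — dissolved oxygen, water temperature,
discharge, surface air pressure, downward shortwave radiation — this module
derives everything else the oxygen model needs: barometric pressure from
elevation, O2 saturation concentration (Garcia-Gordon solubility with a
barometric correction), solar-time conversion, modeled and merged
photosynthetic photon flux density (PPFD), hydraulic-geometry depth and
velocity, percent saturation, and daily aggregates on the 4 a.m.-3:59 a.m.
mean-solar metabolism windows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .timeseries import SiteRecord, TimeSeries

#: ft^3 s^-1 -> m^3 s^-1
CFS_TO_CMS = 0.0283168
#: default shortwave (W m^-2) -> PPFD (umol m^-2 s^-1) multiplier
SW_TO_PAR = 2.114
#: default clear-sky maximum PPFD (umol m^-2 s^-1) for the solar-angle model
PPFD_MAX = 2326.0
#: sea-level standard pressure (Pa)
P_STANDARD = 101325.0
#: metabolism-day boundary: 04:00 mean solar time
DAY_START_HOUR = 4


# ---------------------------------------------------------------------------
# pressure and oxygen solubility


def calc_air_pressure(altitude: float) -> float:
    """Standard-atmosphere air pressure (Pa) at a site elevation (m).

    International standard atmosphere: P = 101325 (1 - 2.25577e-5 h)^5.25588.
    """
    alt = np.asarray(altitude, dtype=float)
    if not np.all(np.isfinite(alt)) or np.any(alt <= -500.0):
        raise ValueError("altitude must be finite and > -500 m")
    p = P_STANDARD * (1.0 - 2.25577e-5 * alt) ** 5.25588
    return float(p) if np.isscalar(altitude) else p


def water_vapor_pressure(water_temp) -> np.ndarray:
    """Saturation water vapor pressure (Pa), Magnus-type formula."""
    t = np.asarray(water_temp, dtype=float)
    return 611.21 * np.exp(17.502 * t / (240.97 + t))


# Garcia & Gordon (1992) Benson-Krause refit, freshwater (salinity terms = 0);
# returns umol O2 per kg at 1 atm moist air.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)


def _water_density(water_temp) -> np.ndarray:
    """Pure-water density (kg L^-1), Kell (1975) polynomial."""
    t = np.asarray(water_temp, dtype=float)
    num = (999.83952 + 16.945176 * t - 7.987040e-3 * t**2
           - 46.170461e-6 * t**3 + 105.56302e-9 * t**4
           - 280.54253e-12 * t**5)
    return num / (1.0 + 16.897850e-3 * t) / 1000.0


def calc_DO_sat(water_temp, pressure=P_STANDARD) -> np.ndarray:
    """Equilibrium (saturation) O2 concentration, mg O2 L^-1.

    Garcia-Gordon solubility at standard pressure, corrected for barometric
    pressure by the moist-air factor (P - pv) / (P0 - pv) where pv is the
    water vapor pressure at the water temperature.

    Parameters
    ----------
    water_temp : array-like, degC (fit range -1..45; outside -> warning)
    pressure : array-like, Pa
    """
    t = np.asarray(water_temp, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be > 0")
    if np.any((t < -1.0) | (t > 45.0)):
        warnings.warn("water temperature outside the solubility fit range "
                      "(-1..45 degC); extrapolating", stacklevel=2)
    ts = np.log((298.15 - t) / (273.15 + t))
    ln_c = np.zeros_like(ts)
    for i, a in enumerate(_GG_A):
        ln_c = ln_c + a * ts**i
    umol_kg = np.exp(ln_c)
    sat_1atm = umol_kg * 32.0e-3 * _water_density(t)  # mg L^-1
    pv = water_vapor_pressure(t)
    out = sat_1atm * (p - pv) / (P_STANDARD - pv)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# solar time and light


def _fractional_year(times: pd.DatetimeIndex) -> np.ndarray:
    doy = times.dayofyear.to_numpy(dtype=float)
    hour = (times.hour + times.minute / 60.0 + times.second / 3600.0).to_numpy(dtype=float)
    return 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)


def equation_of_time(times: pd.DatetimeIndex) -> np.ndarray:
    """Equation of time (minutes), Spencer's Fourier series (<1 min error)."""
    g = _fractional_year(times)
    return 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                     - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))


def solar_declination(times: pd.DatetimeIndex) -> np.ndarray:
    """Solar declination (radians), Spencer's series."""
    g = _fractional_year(times)
    return (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))


def convert_UTC_to_solartime(times, longitude: float, mode: str = "mean"):
    """Convert UTC instants to local solar time (tz-naive).

    Mean solar time shifts by 4 minutes per degree longitude (every day is
    exactly 24 h).  Apparent solar time additionally applies the equation of
    time so that noon coincides with the sun's zenith.
    """
    if mode not in ("mean", "apparent"):
        raise ValueError(f"mode must be 'mean' or 'apparent', got {mode!r}")
    scalar = isinstance(times, pd.Timestamp)
    idx = pd.DatetimeIndex([times]) if scalar else pd.DatetimeIndex(times)
    if idx.tz is None:
        raise ValueError("input instants must be tz-aware UTC")
    idx_utc = idx.tz_convert("UTC").tz_localize(None)
    shift_min = 4.0 * longitude
    out = idx_utc + pd.to_timedelta(shift_min, unit="m")
    if mode == "apparent":
        eot = equation_of_time(idx_utc)
        out = out + pd.to_timedelta(eot, unit="m")
    return out[0] if scalar else out


def calc_light(apparent_solar_times, latitude: float,
               ppfd_max: float = PPFD_MAX) -> np.ndarray:
    """Model above-cloud PPFD (umol m^-2 s^-1) from sun angle.

    PPFD = ppfd_max * max(0, sin(solar elevation)), with the hour angle taken
    directly from apparent solar time (noon = zenith) and declination from
    Spencer's series.  Zero whenever the sun is below the horizon.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude out of range")
    idx = pd.DatetimeIndex(apparent_solar_times)
    if idx.tz is not None:
        raise ValueError("expected tz-naive apparent solar instants")
    decl = solar_declination(idx)
    hours = (idx.hour + idx.minute / 60.0 + idx.second / 3600.0).to_numpy(dtype=float)
    hour_angle = np.deg2rad((hours - 12.0) * 15.0)
    phi = np.deg2rad(latitude)
    sin_el = (np.sin(phi) * np.sin(decl)
              + np.cos(phi) * np.cos(decl) * np.cos(hour_angle))
    return ppfd_max * np.clip(sin_el, 0.0, None)


def convert_SW_to_PAR(sw, multiplier: float = SW_TO_PAR) -> np.ndarray:
    """Shortwave radiation (W m^-2) to PPFD (umol m^-2 s^-1), fixed multiplier."""
    sw = np.clip(np.asarray(sw, dtype=float), 0.0, None)
    return multiplier * sw


def _interp_onto(src_index: pd.DatetimeIndex, src_values: np.ndarray,
                 target_index: pd.DatetimeIndex) -> np.ndarray:
    """Linear interpolation in time; outside the source span -> edge values."""
    x = src_index.asi8.astype(float)
    xt = target_index.asi8.astype(float)
    return np.interp(xt, x, np.asarray(src_values, dtype=float))


def calc_light_merged(modeled: TimeSeries, observed: TimeSeries,
                      eps: float = 1e-9) -> TimeSeries:
    """Downscale coarse observed PPFD using the fine modeled-light shape.

    Multiplies modeled light by the linearly interpolated ratio of observed
    to modeled light, anchored at the coarse timestamps.  Where modeled light
    is zero (night) the ratio is undefined; it is carried across by the
    interpolation and the output is forced to 0 there.
    """
    fine_idx = modeled.timestamps
    fine_val = modeled.values
    coarse_idx = observed.timestamps
    modeled_at_coarse = _interp_onto(fine_idx, fine_val, coarse_idx)
    ratio = np.full(len(coarse_idx), np.nan)
    ok = modeled_at_coarse > eps
    ratio[ok] = observed.values[ok] / modeled_at_coarse[ok]
    if not ok.any():
        ratio[:] = 1.0
    else:
        # carry ratios across night-time coarse points
        s = pd.Series(ratio)
        ratio = s.interpolate(limit_direction="both").to_numpy()
    ratio_fine = _interp_onto(coarse_idx, ratio, fine_idx)
    out = fine_val * ratio_fine
    out[fine_val <= eps] = 0.0
    return TimeSeries("par_calcLatSw",
                      pd.Series(out, index=fine_idx),
                      modeled.resolution_min)


# ---------------------------------------------------------------------------
# hydraulic geometry and saturation


def depth_from_discharge(discharge, coefs: tuple[float, float]) -> np.ndarray:
    """Mean reach depth (m) from discharge (m^3 s^-1): c * Q**f.

    Nonpositive discharge yields NaN (the day is excluded downstream).
    """
    c, f = coefs
    q = np.asarray(discharge, dtype=float)
    out = np.where(q > 0, c * np.power(np.clip(q, 1e-300, None), f), np.nan)
    return out if out.ndim else float(out)


def velocity_from_discharge(discharge, coefs: tuple[float, float]) -> np.ndarray:
    """Mean velocity (m s^-1) from discharge (m^3 s^-1): k * Q**m."""
    return depth_from_discharge(discharge, coefs)


def percent_saturation(doobs, dosat) -> np.ndarray:
    """Percent O2 saturation: 100 * observed / saturation."""
    dosat = np.asarray(dosat, dtype=float)
    if np.any(dosat <= 0):
        raise ValueError("dosat must be > 0")
    out = 100.0 * np.asarray(doobs, dtype=float) / dosat
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# metabolism-day windows and daily aggregation


def metabolism_dates(utc_times, longitude: float) -> np.ndarray:
    """Assign each UTC instant to its metabolism date.

    Days run 04:00-03:59 in *mean* solar time: an observation at mean-solar
    03:30 on calendar date d belongs to metabolism date d-1.
    """
    solar = convert_UTC_to_solartime(pd.DatetimeIndex(utc_times), longitude, "mean")
    return (solar - pd.Timedelta(hours=DAY_START_HOUR)).date


def daily_aggregate(ts: TimeSeries, statistic: str, solar_longitude: float) -> pd.Series:
    """Aggregate a series over 4 a.m.-3:59 a.m. mean-solar windows.

    statistic: 'mean', 'range', or 'count_positive_hours' (hours with
    value > 0; used for daylight hours of PPFD).
    """
    if statistic not in ("mean", "range", "count_positive_hours"):
        raise ValueError(f"unknown statistic {statistic!r}")
    dates = metabolism_dates(ts.timestamps, solar_longitude)
    df = pd.DataFrame({"date": dates, "value": ts.values})
    g = df.groupby("date")["value"]
    if statistic == "mean":
        out = g.mean()
    elif statistic == "range":
        out = g.max() - g.min()
    else:
        step_h = (ts.resolution_min or 60.0) / 60.0
        out = g.apply(lambda v: float((v > 0).sum()) * step_h)
    out.index = pd.Index(out.index, name="date")
    return out


# ---------------------------------------------------------------------------
# full Table-of-derived-variables pipeline


def derive_forcings(site: SiteRecord, raws: dict[str, TimeSeries],
                    sw_to_par: float = SW_TO_PAR,
                    ppfd_max: float = PPFD_MAX) -> dict[str, TimeSeries]:
    """Compute every derived forcing series from the raw series alone.

    Expects raw keys doobs_nwis, wtr_nwis, disch_nwis, and baro/sw from
    either the fine-resolution or global climate product (``*_nldas``
    preferred over ``*_gldas``).  Returns a dict of derived TimeSeries keyed
    by variable name, each on its natural timestamp grid.
    """
    def pick(prefix):
        for suffix in ("nldas", "gldas"):
            key = f"{prefix}_{suffix}"
            if key in raws:
                return raws[key]
        raise KeyError(f"missing raw variable {prefix}_nldas/{prefix}_gldas")

    o2 = raws["doobs_nwis"]
    wtr = raws["wtr_nwis"]
    disch = raws["disch_nwis"]
    baro = pick("baro")
    sw = pick("sw")

    out: dict[str, TimeSeries] = {}

    disch_cms = disch.values * CFS_TO_CMS
    depth = depth_from_discharge(disch_cms, site.depth_coefs)
    veloc = velocity_from_discharge(disch_cms, site.veloc_coefs)
    out["depth_calcDischHarvey"] = TimeSeries(
        "depth_calcDischHarvey", pd.Series(depth, index=disch.timestamps),
        disch.resolution_min)
    out["veloc_calcDischHarvey"] = TimeSeries(
        "veloc_calcDischHarvey", pd.Series(veloc, index=disch.timestamps),
        disch.resolution_min)

    baro_at_wtr = _interp_onto(baro.timestamps, baro.values, wtr.timestamps)
    dosat = calc_DO_sat(wtr.values, baro_at_wtr)
    out["dosat_calcGGbts"] = TimeSeries(
        "dosat_calcGGbts", pd.Series(dosat, index=wtr.timestamps),
        wtr.resolution_min)

    dosat_at_o2 = _interp_onto(wtr.timestamps, dosat, o2.timestamps)
    out["dopsat_calcObsSat"] = TimeSeries(
        "dopsat_calcObsSat",
        pd.Series(percent_saturation(o2.values, dosat_at_o2), index=o2.timestamps),
        o2.resolution_min)

    out["par_calcSw"] = TimeSeries(
        "par_calcSw", pd.Series(convert_SW_to_PAR(sw.values, sw_to_par),
                                index=sw.timestamps), sw.resolution_min)

    suntime = convert_UTC_to_solartime(o2.timestamps, site.longitude, "apparent")
    par_lat = calc_light(suntime, site.latitude, ppfd_max)
    out["par_calcLat"] = TimeSeries(
        "par_calcLat", pd.Series(par_lat, index=o2.timestamps), o2.resolution_min)

    out["par_calcLatSw"] = calc_light_merged(out["par_calcLat"], out["par_calcSw"])
    return out


def daily_forcing_summaries(site: SiteRecord, raws: dict[str, TimeSeries],
                            derived: dict[str, TimeSeries]) -> pd.DataFrame:
    """Daily predictor aggregates on metabolism windows (one row per date)."""
    lon = site.longitude
    sw = raws.get("sw_nldas", raws.get("sw_gldas"))
    disch = raws["disch_nwis"]
    disch_cms = TimeSeries("disch_cms",
                           pd.Series(disch.values * CFS_TO_CMS, index=disch.timestamps),
                           disch.resolution_min)
    cols = {
        "doobs_daily_mean": daily_aggregate(raws["doobs_nwis"], "mean", lon),
        "dosat_daily_mean": daily_aggregate(derived["dosat_calcGGbts"], "mean", lon),
        "wtr_daily_mean": daily_aggregate(raws["wtr_nwis"], "mean", lon),
        "swdaily_calcDMean": daily_aggregate(sw, "mean", lon),
        "depth_daily_mean": daily_aggregate(derived["depth_calcDischHarvey"], "mean", lon),
        "dischdaily_calcDMean": daily_aggregate(disch_cms, "mean", lon),
        "velocdaily_calcDMean": daily_aggregate(derived["veloc_calcDischHarvey"], "mean", lon),
        "doamp_calcDAmp": daily_aggregate(derived["dopsat_calcObsSat"], "range", lon),
        "daylight_hours": daily_aggregate(derived["par_calcLatSw"],
                                          "count_positive_hours", lon),
    }
    return pd.DataFrame(cols)
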