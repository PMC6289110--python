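"""Readers and writers for the release-style tab-delimited tables.

Layout mirrors a public metabolism data release: one two-column file per
site-variable (``<siteid>_<variable>.tsv``, ISO-8601 UTC DateTime + value),
one merged model-input table per site and resolution chunk, a four-part
output bundle per fitted model (daily / nodes / overall tables + metadata
text), a one-row-per-model diagnostics table, and a combined daily
estimates-and-predictors table.  Every writer has a matching reader
(schema closure) and missing values are encoded as NA.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .input_prep import DayValidity, ModelInput
from .timeseries import TimeSeries, make_timeseries

NA = "NA"


def timeseries_path(directory: str, site_id: str, variable: str) -> str:
    return os.path.join(directory, f"{site_id}_{variable}.tsv")


def write_timeseries(ts: TimeSeries, path: str) -> None:
    """Write a two-column DateTime/value file (tab-delimited, UTC)."""
    with open(path, "w") as fh:
        fh.write("DateTime\tvalue\n")
        stamps = ts.timestamps.strftime("%Y-%m-%dT%H:%M:%SZ")
        for t, v in zip(stamps, ts.values):
            fh.write(f"{t}\t{float(v)!r}\n")


def read_timeseries(path: str) -> TimeSeries:
    """Read a site-variable file; the variable name is parsed from the filename."""
    fname = os.path.basename(path)
    stem = fname.rsplit(".", 1)[0]
    try:
        _, variable = stem.split("_", 1)
    except ValueError:
        raise ValueError(f"cannot parse '<siteid>_<variable>' from {fname!r}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != ["DateTime", "value"]:
        raise ValueError(f"{path}: expected columns DateTime, value")
    stamps = pd.to_datetime(df["DateTime"], utc=True, errors="coerce",
                            format="ISO8601")
    bad = stamps.isna()
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed timestamp at line {line}")
    return make_timeseries(variable, stamps, df["value"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# site metadata


def write_site_record(site, path: str) -> None:
    data = {"site_id": site.site_id, "latitude": site.latitude,
            "longitude": site.longitude, "altitude": site.altitude,
            "depth_coefs": list(site.depth_coefs),
            "veloc_coefs": list(site.veloc_coefs)}
    if site.structure_distances:
        data["structure_distances"] = dict(site.structure_distances)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_site_record(path: str):
    from .timeseries import SiteRecord
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SiteRecord(d["site_id"], d["latitude"], d["longitude"], d["altitude"],
                      tuple(d["depth_coefs"]), tuple(d["veloc_coefs"]),
                      d.get("structure_distances"))


# ---------------------------------------------------------------------------
# model inputs


def write_model_input(mi: ModelInput, path: str) -> None:
    df = mi.table.copy()
    df.insert(0, "DateTime", df.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
    df["sitetime"] = df["sitetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["date"] = df["date"].astype(str)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)
    mpath = path.rsplit(".", 1)[0] + "_messages.tsv"
    mi.messages().to_csv(mpath, sep="\t", index=False, na_rep=NA)


def read_model_input(path: str) -> ModelInput:
    df = pd.read_csv(path, sep="\t", na_values=[NA],
                     float_precision="round_trip")
    idx = pd.DatetimeIndex(pd.to_datetime(df.pop("DateTime"), utc=True))
    df.index = idx
    df["sitetime"] = pd.to_datetime(df["sitetime"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    res = float(np.median(np.diff(idx.asi8)) / 60e9)
    mpath = path.rsplit(".", 1)[0] + "_messages.tsv"
    validity = []
    msgs = pd.read_csv(mpath, sep="\t", na_values=[NA], keep_default_na=False)
    for _, row in msgs.iterrows():
        reason = "none"
        if not row["valid"]:
            reason = str(row["message"]).replace("excluded: ", "")
        validity.append(DayValidity(pd.to_datetime(row["date"]).date(),
                                    bool(row["valid"]), reason))
    return ModelInput(df, res, validity)


# ---------------------------------------------------------------------------
# fit bundle (daily + nodes + overall + metadata)


def write_fit_bundle(fit, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    daily = fit.daily.copy()
    daily["date"] = daily["date"].astype(str)
    daily.to_csv(os.path.join(directory, "daily.tsv"), sep="\t",
                 index=False, na_rep=NA)
    fit.nodes.to_csv(os.path.join(directory, "nodes.tsv"), sep="\t",
                     index=False, na_rep=NA)
    fit.overall.to_csv(os.path.join(directory, "overall.tsv"), sep="\t",
                       index=False, na_rep=NA)
    with open(os.path.join(directory, "metadata.txt"), "w") as fh:
        for k, v in fit.metadata.items():
            fh.write(f"{k}: {v}\n")


def read_fit_bundle(directory: str) -> dict[str, pd.DataFrame]:
    out = {}
    for name in ("daily", "nodes", "overall"):
        df = pd.read_csv(os.path.join(directory, f"{name}.tsv"), sep="\t",
                         na_values=[NA])
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"]).dt.date
        out[name] = df
    meta = {}
    with open(os.path.join(directory, "metadata.txt")) as fh:
        for line in fh:
            k, _, v = line.partition(":")
            meta[k.strip()] = v.strip()
    out["metadata"] = meta
    return out


# ---------------------------------------------------------------------------
# combined daily estimates + predictors (4 significant digits)


def _fmt4(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return NA
    return f"{x:.4g}" if isinstance(x, (float, np.floating)) else str(x)


def write_daily_estimates(fit, predictors: pd.DataFrame, path: str,
                          site_id: str = "site") -> None:
    """Item-8-style table: one row per valid site-date, params + predictors.

    ``predictors`` is indexed by metabolism date (missing predictor values
    are written as NA).  Percentile ordering is enforced on write.
    """
    rows = []
    dates = fit.daily_param("GPP").index if len(fit.daily) else []
    for date in dates:
        row = {"site_id": site_id, "date": str(date)}
        for pname in ("GPP", "ER", "K600"):
            s = fit.daily_param(pname).loc[date]
            lo, mid, hi = sorted([s["2.5%"], s["50%"], s["97.5%"]])
            row[f"{pname}.lower"] = lo
            row[f"{pname}.50"] = mid
            row[f"{pname}.upper"] = hi
            row[f"{pname}.Rhat"] = s["Rhat"]
            row[f"{pname}.n_eff"] = s["n_eff"]
        if date in predictors.index:
            for col in predictors.columns:
                row[col] = predictors.loc[date, col]
        else:
            for col in predictors.columns:
                row[col] = np.nan
        rows.append(row)
    if rows:
        cols = list(rows[0].keys())
    else:
        cols = ["site_id", "date"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt4(row[c]) for c in cols) + "\n")


def read_daily_estimates(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_diagnostics(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_diagnostics(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])
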