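"""Model assessment: reach lengths, confidence rating, structure interference.

A single-station estimate integrates over the upstream reach in which the
O2 pool turns over; the daily reach length is the distance for 80% gas
renewal, L_d = -ln(1 - 0.8) * v / KO2_d.  Each fitted model is rated Low,
Medium or High confidence from four metrics: convergence (max Rhat of the
two key sd parameters), the P90-P10 spread of daily K600 (gas exchange is
constrained by channel form, so large spread is physically suspect), and the
percentages of biologically unrealistic daily rates (GPP < -0.5 or
ER > 0.5 g O2 m^-2 d^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult
from .oxygen_model import K600_to_KO2

CONFIDENCE_ORDER = {"Low": 0, "Medium": 1, "High": 2}

#: structure-interference classes, ordered by the reach-length percentile
#: that the structure distance exceeds
PERCENTILE_CLASSES = ("P0", "P50", "P80", "P95")


def reach_length(velocity, ko2, renewal_fraction: float = 0.8) -> np.ndarray:
    """Daily reach length (m): L = -ln(1 - fraction) * v / KO2.

    velocity in m d^-1, KO2 in d^-1.
    """
    v = np.asarray(velocity, dtype=float)
    k = np.asarray(ko2, dtype=float)
    if np.any(v <= 0) or np.any(k <= 0):
        raise ValueError("velocity and KO2 must be positive")
    out = -np.log(1.0 - renewal_fraction) * v / k
    return out if out.ndim else float(out)


@dataclass
class AssessmentRecord:
    model_id: str
    rhat_max_key: float
    k600_range: float       # P90 - P10 of daily K600 medians, d^-1
    pct_gpp_neg: float      # % of daily GPP medians < -0.5
    pct_er_pos: float       # % of daily ER medians > 0.5
    median_k600: float
    run_hours: float
    confidence: str = ""

    def __post_init__(self):
        for v, name in ((self.pct_gpp_neg, "pct_gpp_neg"),
                        (self.pct_er_pos, "pct_er_pos")):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")


def assess_confidence(rhat_max_key: float, k600_range: float,
                      pct_gpp_neg: float, pct_er_pos: float) -> str:
    """Confidence label from the four assessment metrics.

    Low if any metric falls in its Low band (Rhat > 1.2, K600 range > 50,
    either unrealistic-rate percentage > 50); High only if every metric is
    in its High band (Rhat < 1.2, range < 15, percentages < 25); Medium
    otherwise.  Thresholds are strict inequalities, so boundary values fall
    to Medium.
    """
    metrics = (rhat_max_key, k600_range, pct_gpp_neg, pct_er_pos)
    if any(v is None or not np.isfinite(v) for v in metrics):
        raise ValueError("all four assessment metrics are required")
    if (rhat_max_key > 1.2 or k600_range > 50.0
            or pct_gpp_neg > 50.0 or pct_er_pos > 50.0):
        return "Low"
    if (rhat_max_key < 1.2 and k600_range < 15.0
            and pct_gpp_neg < 25.0 and pct_er_pos < 25.0):
        return "High"
    return "Medium"


def site_confidence(model_labels: list[str]) -> tuple[str, str]:
    """(minimum confidence, comma-joined per-model labels) for one site."""
    if not model_labels:
        raise ValueError("need at least one model")
    minimum = min(model_labels, key=lambda s: CONFIDENCE_ORDER[s])
    return minimum, ",".join(model_labels)


def structure_interference(distance_m: float | None,
                           daily_reach_lengths) -> str:
    """Classify a structure distance against the reach-length distribution.

    Returns the highest class in P0 < P50 < P80 < P95 whose reach-length
    percentile the distance strictly exceeds; P0 means the structure sits
    within the daily reach on at least half the days.  An unknown/absent
    structure is reported as beyond P95.  Ties resolve to the lower class.
    """
    if distance_m is None:
        return "P95"
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    lengths = np.asarray(daily_reach_lengths, dtype=float)
    if lengths.size < 1:
        raise ValueError("need at least one daily reach length")
    cls = "P0"
    for pct, label in ((50, "P50"), (80, "P80"), (95, "P95")):
        if distance_m > np.percentile(lengths, pct):
            cls = label
    return cls


def assess_fit(fit: FitResult, model_id: str = "model") -> AssessmentRecord:
    """Compute the assessment metrics and confidence label for one fit.

    K600 spread and unrealistic-rate percentages are computed from the daily
    posterior medians (the release's central estimates).
    """
    k600 = fit.daily_param("K600")["50%"].to_numpy()
    gpp = fit.daily_param("GPP")["50%"].to_numpy()
    er = fit.daily_param("ER")["50%"].to_numpy()
    rec = AssessmentRecord(
        model_id=model_id,
        rhat_max_key=fit.key_rhat,
        k600_range=float(np.percentile(k600, 90) - np.percentile(k600, 10)),
        pct_gpp_neg=float(100.0 * np.mean(gpp < -0.5)),
        pct_er_pos=float(100.0 * np.mean(er > 0.5)),
        median_k600=float(np.median(k600)),
        run_hours=fit.metadata.get("runtime_s", np.nan) / 3600.0,
    )
    rec.confidence = assess_confidence(rec.rhat_max_key, rec.k600_range,
                                       rec.pct_gpp_neg, rec.pct_er_pos)
    return rec


def daily_reach_lengths(fit: FitResult, daily_velocity_m_s: pd.Series,
                        daily_wtr: pd.Series,
                        renewal_fraction: float = 0.8) -> pd.Series:
    """Per-date 80% turnover distances from daily K600 medians.

    ``daily_velocity_m_s`` (m s^-1) and ``daily_wtr`` (degC) are indexed by
    metabolism date; only dates present in the fit are returned.
    """
    k600 = fit.daily_param("K600")["50%"]
    dates = k600.index
    v = daily_velocity_m_s.reindex(dates).to_numpy() * 86400.0  # m d^-1
    ko2 = K600_to_KO2(k600.to_numpy(), daily_wtr.reindex(dates).to_numpy())
    return pd.Series(reach_length(v, ko2, renewal_fraction), index=dates,
                     name="reach_length_m")


def diagnostics_table(records: list[AssessmentRecord]) -> pd.DataFrame:
    """One-row-per-model diagnostics table."""
    return pd.DataFrame([{
        "model_id": r.model_id, "rhat_max_key": r.rhat_max_key,
        "K600_range_P90_P10": r.k600_range, "pct_GPP_below_neg0.5": r.pct_gpp_neg,
        "pct_ER_above_0.5": r.pct_er_pos, "median_K600": r.median_k600,
        "run_hours": r.run_hours, "confidence": r.confidence,
    } for r in records])
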