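"""Forward model of diel dissolved oxygen and its state-space likelihood.

The rate of change of reach-averaged O2 on day d at timestep i is

    dO/dt = GPP_d / z_i * PPFD_i / mean(PPFD_d)  +  ER_d / z_i
            +  KO2_i * (Osat_i - O_i)

with GPP_d and ER_d in g O2 m^-2 d^-1, depth z in m, and the gas exchange
coefficient KO2 (d^-1) obtained from the daily K600_d by Schmidt-number
scaling.  The equation is integrated with the trapezoid rule; because gas
exchange is linear in O, the implicit step has a closed-form solution.  The
state-space formulation adds iid Gaussian process error to each step of the
latent O2 state and iid Gaussian observation error to each measurement.
Conditional on the daily parameters this is a linear-Gaussian system, so the
latent states can be marginalised exactly with a scalar Kalman filter
(:func:`kalman_loglik`), which is what the sampler uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .input_prep import ModelInput

_LOG2PI = float(np.log(2.0 * np.pi))

# freshwater O2 Schmidt number polynomial coefficients (T in degC)
_SC_COEFS = (1568.0, -86.04, 2.142, -0.0216)


def schmidt_number_O2(water_temp) -> np.ndarray:
    """Schmidt number of O2 in fresh water at temperature T (degC).

    Third-order polynomial fit, valid 0-40 degC; Sc(20) = 531.2 and the
    polynomial crosses 600 near 17.5 degC.
    """
    t = np.asarray(water_temp, dtype=float)
    a0, a1, a2, a3 = _SC_COEFS
    out = a0 + a1 * t + a2 * t**2 + a3 * t**3
    return out if out.ndim else float(out)


def K600_to_KO2(k600, water_temp) -> np.ndarray:
    """Convert K600 (d^-1) to the O2-specific coefficient: K600*(Sc/600)^-0.5."""
    k600 = np.asarray(k600, dtype=float)
    out = k600 * (schmidt_number_O2(water_temp) / 600.0) ** -0.5
    return out if out.ndim else float(out)


@dataclass
class DayData:
    """Valid metabolism days stacked as (n_days, n_steps_per_day) arrays."""

    dates: list
    dt_days: float
    obs: np.ndarray     # observed O2, mg L^-1
    depth: np.ndarray   # m
    ppfd: np.ndarray    # umol m^-2 s^-1
    osat: np.ndarray    # mg L^-1
    wtr: np.ndarray     # degC
    daily_lnq: np.ndarray  # ln of daily mean discharge (m^3 s^-1), (n_days,)

    @property
    def n_days(self) -> int:
        return self.obs.shape[0]

    @property
    def light_frac(self) -> np.ndarray:
        """PPFD_i / mean(PPFD_d); zero if a day has no light."""
        mean_ppfd = self.ppfd.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            lf = np.where(mean_ppfd > 0, self.ppfd / mean_ppfd, 0.0)
        return lf


def stack_days(mi: ModelInput) -> DayData:
    """Extract the valid days of a ModelInput into dense arrays."""
    dates = mi.valid_dates
    if not dates:
        raise ValueError("no valid days to fit")
    cols = ("doobs", "depth", "ppfd", "dosat", "wtr", "discharge")
    stacks = {c: [] for c in cols}
    for d in dates:
        day = mi.day_rows(d)
        for c in cols:
            stacks[c].append(day[c].to_numpy(dtype=float))
    arrs = {c: np.vstack(v) for c, v in stacks.items()}
    if np.any(arrs["depth"] <= 0):
        raise ValueError("nonpositive depth in valid days")
    return DayData(
        dates=dates,
        dt_days=mi.resolution_min / 1440.0,
        obs=arrs["doobs"],
        depth=arrs["depth"],
        ppfd=arrs["ppfd"],
        osat=arrs["dosat"],
        wtr=arrs["wtr"],
        daily_lnq=np.log(arrs["discharge"].mean(axis=1)),
    )


def _step_coefficients(gpp, er, k600, depth, light_frac, osat, wtr, dt_days):
    """Closed-form trapezoid update O_{i+1} = a_i O_i + b_i.

    All of depth/light_frac/osat/wtr have a trailing timestep axis of length
    m; gpp/er/k600 broadcast against the leading axes.  Returns (a, b) with
    trailing axis m-1.
    """
    gpp = np.asarray(gpp, dtype=float)[..., None]
    er = np.asarray(er, dtype=float)[..., None]
    k600 = np.asarray(k600, dtype=float)[..., None]
    ko2 = k600 * (schmidt_number_O2(wtr) / 600.0) ** -0.5
    source = gpp * light_frac / depth + er / depth + ko2 * osat
    half = 0.5 * dt_days
    denom = 1.0 + half * ko2[..., 1:]
    a = (1.0 - half * ko2[..., :-1]) / denom
    b = half * (source[..., :-1] + source[..., 1:]) / denom
    return a, b


def simulate_day(gpp: float, er: float, k600: float, depth, ppfd, osat, wtr,
                 dt_days: float, init_o: float,
                 process_noise=None) -> np.ndarray:
    """Integrate one day of modeled O2 with the trapezoid rule.

    ``depth``/``ppfd``/``osat``/``wtr`` are per-timestep arrays of equal
    length m; returns the modeled path (length m) starting at ``init_o``.
    ``process_noise``, if given, is an array of m-1 per-step additive draws.
    If the day has no light (mean PPFD = 0) the GPP term is zero.
    """
    depth = np.asarray(depth, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive")
    if not (len(depth) == len(ppfd) == len(osat) == len(wtr)):
        raise ValueError("input arrays must share one length")
    mean_ppfd = ppfd.mean()
    lf = ppfd / mean_ppfd if mean_ppfd > 0 else np.zeros_like(ppfd)
    a, b = _step_coefficients(gpp, er, k600, depth, lf,
                              np.asarray(osat, dtype=float),
                              np.asarray(wtr, dtype=float), dt_days)
    m = len(depth)
    path = np.empty(m)
    path[0] = init_o
    for i in range(m - 1):
        path[i + 1] = a[i] * path[i] + b[i]
        if process_noise is not None:
            path[i + 1] += process_noise[i]
    if np.any(path < 0):
        warnings.warn("modeled O2 went negative", stacklevel=2)
    return path


def state_space_logdensity(gpp, er, k600, states, sigma_obs: float,
                           sigma_proc: float, dd: DayData) -> float:
    """Joint log density of latent states and observations given daily params.

    ``states`` has the same (n_days, m) shape as ``dd.obs`` and its first
    column is the per-day initial state (pinned to the first observation by
    convention).  Process terms penalise deviations between successive states
    and their deterministic trapezoid predictions (sd ``sigma_proc``);
    observation terms penalise obs - state (sd ``sigma_obs``).  Priors are
    added by the inference module.
    """
    states = np.asarray(states, dtype=float)
    a, b = _step_coefficients(np.asarray(gpp), np.asarray(er), np.asarray(k600),
                              dd.depth, dd.light_frac, dd.osat, dd.wtr,
                              dd.dt_days)
    pred = a * states[..., :-1] + b
    eps_p = states[..., 1:] - pred
    eps_o = dd.obs - states
    n_p = eps_p.size
    n_o = eps_o.size
    ll_p = -0.5 * (n_p * (_LOG2PI + 2 * np.log(sigma_proc))
                   + np.sum(eps_p**2) / sigma_proc**2)
    ll_o = -0.5 * (n_o * (_LOG2PI + 2 * np.log(sigma_obs))
                   + np.sum(eps_o**2) / sigma_obs**2)
    return float(ll_p + ll_o)


def kalman_loglik(gpp, er, k600, sigma_obs, sigma_proc, dd: DayData) -> np.ndarray:
    """Marginal log likelihood of the observations, states integrated out.

    Batched: gpp/er/k600 have shape (..., n_days) and sigma_obs/sigma_proc
    shape (...,); returns shape (...,).  Each day's initial state is pinned
    to its first observation, then a scalar Kalman filter runs over the
    remaining m-1 steps.
    """
    gpp = np.asarray(gpp, dtype=float)
    a, b = _step_coefficients(gpp, np.asarray(er), np.asarray(k600),
                              dd.depth, dd.light_frac, dd.osat, dd.wtr,
                              dd.dt_days)
    so2 = np.asarray(sigma_obs, dtype=float)[..., None] ** 2
    sp2 = np.asarray(sigma_proc, dtype=float)[..., None] ** 2
    batch = a.shape[:-1]  # (..., n_days)
    mu = np.broadcast_to(dd.obs[..., 0], batch).copy()
    P = np.zeros(batch)
    ll = np.zeros(batch)
    m = dd.obs.shape[-1]
    for i in range(m - 1):
        ai = a[..., i]
        mu = ai * mu + b[..., i]
        P = ai * ai * P + sp2
        innov = dd.obs[..., i + 1] - mu
        V = P + so2
        ll += -0.5 * (_LOG2PI + np.log(V) + innov * innov / V)
        gain = P / V
        mu = mu + gain * innov
        P = (1.0 - gain) * P
    return ll.sum(axis=-1)
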