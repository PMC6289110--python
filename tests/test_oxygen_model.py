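"""Forward O2 model: Schmidt scaling, trapezoid integration, likelihoods."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import multivariate_normal

from rivermetab import (K600_to_KO2, kalman_loglik, schmidt_number_O2,
                        simulate_day, state_space_logdensity)
from rivermetab.oxygen_model import _step_coefficients

from conftest import make_toy_day


def fine_reference_path(gpp, er, k600, depth, ppfd, osat, wtr, dt_days,
                        init_o, refine=100):
    """Independent oracle: trapezoid on a `refine`-times finer grid with
    linearly interpolated inputs."""
    depth = np.asarray(depth, float)
    ppfd = np.asarray(ppfd, float)
    m = len(depth)
    mean_ppfd = ppfd.mean()
    lf = ppfd / mean_ppfd if mean_ppfd > 0 else np.zeros(m)
    ko2 = K600_to_KO2(k600, np.asarray(wtr, float))
    src = gpp * lf / depth + er / depth + ko2 * np.asarray(osat, float)
    h = dt_days / refine
    o = init_o
    out = [o]
    for i in range(m - 1):
        for j in range(refine):
            f0, f1 = j / refine, (j + 1) / refine
            s0 = src[i] + (src[i + 1] - src[i]) * f0
            s1 = src[i] + (src[i + 1] - src[i]) * f1
            k0 = ko2[i] + (ko2[i + 1] - ko2[i]) * f0
            k1 = ko2[i] + (ko2[i + 1] - ko2[i]) * f1
            o = (o * (1 - h / 2 * k0) + h / 2 * (s0 + s1)) / (1 + h / 2 * k1)
        out.append(o)
    return np.array(out)


def _diel_inputs(m=96, seed=0):
    rng = np.random.default_rng(seed)
    tt = np.arange(m) / m * 24.0
    ppfd = np.clip(np.sin((tt - 6) / 12 * np.pi), 0, None) * rng.uniform(500, 2000)
    wtr = 15 + 5 * np.sin((tt - 10) / 24 * 2 * np.pi)
    osat = 9 + 0.5 * np.sin(tt / 24 * 2 * np.pi)
    depth = np.full(m, rng.uniform(0.3, 2.0))
    return depth, ppfd, osat, wtr


class TestSchmidtScaling:
    def test_schmidt_number_at_20C(self):
        # 1568 - 86.04*20 + 2.142*400 - 0.0216*8000 = 531.2
        assert schmidt_number_O2(20.0) == pytest.approx(531.2, abs=0.5)

    def test_schmidt_600_crossing_near_17_5C(self):
        t600 = brentq(lambda t: schmidt_number_O2(t) - 600.0, 10, 25)
        assert t600 == pytest.approx(17.5, rel=0.02)

    def test_decreasing_in_temperature(self):
        assert schmidt_number_O2(30.0) < schmidt_number_O2(10.0)
        t = np.linspace(0, 40, 81)
        assert np.all(np.diff(schmidt_number_O2(t)) < 0)

    def test_ko2_identity_at_sc600(self):
        t600 = brentq(lambda t: schmidt_number_O2(t) - 600.0, 10, 25)
        assert K600_to_KO2(7.3, t600) == pytest.approx(7.3, abs=1e-9)

    def test_ko2_values(self):
        assert K600_to_KO2(10.0, 20.0) == pytest.approx(10.63, abs=0.01)
        assert K600_to_KO2(0.0, 12.0) == 0.0


class TestSimulateDay:
    def test_equilibrium_fixed_point(self):
        # GPP=ER=0 and strong gas exchange: O converges to Osat within a day
        m = 96
        depth = np.full(m, 0.5)
        osat = np.full(m, 9.2)
        path = simulate_day(0.0, 0.0, 50.0, depth, np.zeros(m), osat,
                            np.full(m, 17.5), 1 / 96, init_o=6.0)
        assert abs(path[-1] - 9.2) < 1e-3

    def test_pure_source_linear_drift(self):
        # K600=0, constant depth: net drift is (GPP+ER)/z per day
        m = 96
        z = 0.8
        path = simulate_day(6.0, -4.0, 0.0, np.full(m, z), np.full(m, 100.0),
                            np.full(m, 9.0), np.full(m, 15.0), 1 / 96, 8.0)
        expected = (6.0 - 4.0) / z * (m - 1) / 96
        assert path[-1] - path[0] == pytest.approx(expected, abs=1e-12)

    def test_full_diel_case_matches_fine_oracle(self):
        depth, ppfd, osat, wtr = _diel_inputs(seed=3)
        args = (5.0, -8.0, 15.0, np.full(96, 0.5), ppfd, osat, wtr, 1 / 96, 8.5)
        coarse = simulate_day(*args)
        fine = fine_reference_path(*args)
        assert np.max(np.abs(coarse - fine)) < 0.02

    def test_matches_fine_oracle_across_random_parameters(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for trial in range(50):
            depth, ppfd, osat, wtr = _diel_inputs(seed=trial)
            gpp = rng.uniform(0, 10)
            er = rng.uniform(-15, 0)
            k600 = rng.uniform(0.5, 35)
            init = rng.uniform(7, 11)
            args = (gpp, er, k600, depth, ppfd, osat, wtr, 1 / 96, init)
            worst = max(worst, np.max(np.abs(
                simulate_day(*args) - fine_reference_path(*args))))
        assert worst < 0.02

    def test_time_reversible_without_gas_exchange(self):
        depth, ppfd, osat, wtr = _diel_inputs(seed=7)
        fwd = simulate_day(4.0, -6.0, 0.0, depth, ppfd, osat, wtr, 1 / 96, 9.0)
        # integrate backward: with K600=0 the update is O_{i+1} = O_i + b_i
        bwd = simulate_day(-4.0, 6.0, 0.0, depth[::-1], ppfd[::-1],
                           osat[::-1], wtr[::-1], 1 / 96, fwd[-1])
        assert bwd[-1] == pytest.approx(9.0, abs=1e-12)

    def test_gas_exchange_direction(self):
        # with GPP=ER=0, dO always points toward saturation
        depth, ppfd, osat, wtr = _diel_inputs(seed=9)
        for init in (6.0, 12.0):
            path = simulate_day(0.0, 0.0, 8.0, depth, np.zeros_like(ppfd),
                                osat, wtr, 1 / 96, init)
            d_o = np.diff(path)
            mid_osat = 0.5 * (osat[:-1] + osat[1:])
            mid_o = 0.5 * (path[:-1] + path[1:])
            assert np.all(np.sign(d_o) == np.sign(mid_osat - mid_o))

    def test_dark_day_has_no_gpp_term(self):
        m = 48
        z = np.full(m, 0.5)
        dark = simulate_day(5.0, -3.0, 0.0, z, np.zeros(m), np.full(m, 9.0),
                            np.full(m, 15.0), 1 / 48, 8.0)
        no_gpp = simulate_day(0.0, -3.0, 0.0, z, np.zeros(m), np.full(m, 9.0),
                              np.full(m, 15.0), 1 / 48, 8.0)
        assert np.allclose(dark, no_gpp)

    def test_nonpositive_depth_rejected(self):
        m = 8
        with pytest.raises(ValueError, match="depth"):
            simulate_day(1.0, -1.0, 5.0, np.zeros(m), np.ones(m),
                         np.full(m, 9.0), np.full(m, 15.0), 1 / 96, 8.0)


class TestStateSpaceDensity:
    def test_deterministic_path_is_modal_as_process_error_vanishes(self):
        dd = make_toy_day(m=6)
        det = simulate_day(3.0, -5.0, 10.0, dd.depth[0], dd.ppfd[0],
                           dd.osat[0], dd.wtr[0], dd.dt_days, dd.obs[0, 0])
        perturbed = det.copy()
        perturbed[3] += 0.01
        for sp in (1e-3, 1e-5):
            ll_det = state_space_logdensity(3.0, -5.0, 10.0, det[None], 0.1, sp, dd)
            ll_pert = state_space_logdensity(3.0, -5.0, 10.0, perturbed[None],
                                             0.1, sp, dd)
            assert ll_det > ll_pert
        # and the gap widens as sigma_proc -> 0
        gap = [state_space_logdensity(3.0, -5.0, 10.0, det[None], 0.1, sp, dd)
               - state_space_logdensity(3.0, -5.0, 10.0, perturbed[None], 0.1, sp, dd)
               for sp in (1e-2, 1e-3, 1e-4)]
        assert gap[0] < gap[1] < gap[2]

    def test_doubled_residuals_lower_density_by_quadratic_amount(self):
        dd = make_toy_day(m=4)
        det = simulate_day(2.0, -4.0, 8.0, dd.depth[0], dd.ppfd[0], dd.osat[0],
                           dd.wtr[0], dd.dt_days, dd.obs[0, 0])
        states1 = det + np.array([0.0, 0.02, -0.01, 0.015])
        states2 = det + 2 * np.array([0.0, 0.02, -0.01, 0.015])
        so, sp = 0.05, 0.03
        a, b = _step_coefficients(2.0, -4.0, 8.0, dd.depth, dd.light_frac,
                                  dd.osat, dd.wtr, dd.dt_days)

        def quad(states):
            eps_p = states[1:] - (a[0] * states[:-1] + b[0])
            eps_o = dd.obs[0] - states
            return -0.5 * (np.sum(eps_p**2) / sp**2 + np.sum(eps_o**2) / so**2)

        ll1 = state_space_logdensity(2.0, -4.0, 8.0, states1[None], so, sp, dd)
        ll2 = state_space_logdensity(2.0, -4.0, 8.0, states2[None], so, sp, dd)
        assert ll2 - ll1 == pytest.approx(quad(states2) - quad(states1), abs=1e-9)

    def test_density_invariant_to_day_permutation(self):
        rng = np.random.default_rng(1)
        d1 = make_toy_day(m=5, seed=1)
        d2 = make_toy_day(m=5, seed=2)
        from rivermetab.oxygen_model import DayData
        stack = lambda a, b: np.vstack([a, b])
        fwd = DayData(["a", "b"], d1.dt_days, stack(d1.obs, d2.obs),
                      stack(d1.depth, d2.depth), stack(d1.ppfd, d2.ppfd),
                      stack(d1.osat, d2.osat), stack(d1.wtr, d2.wtr),
                      np.array([1.0, 2.0]))
        rev = DayData(["b", "a"], d1.dt_days, stack(d2.obs, d1.obs),
                      stack(d2.depth, d1.depth), stack(d2.ppfd, d1.ppfd),
                      stack(d2.osat, d1.osat), stack(d2.wtr, d1.wtr),
                      np.array([2.0, 1.0]))
        gpp = np.array([3.0, 4.0])
        er = np.array([-5.0, -6.0])
        k = np.array([9.0, 11.0])
        states = rng.standard_normal((2, 5)) * 0.1 + 9.0
        ll_f = state_space_logdensity(gpp, er, k, states, 0.1, 0.05, fwd)
        ll_r = state_space_logdensity(gpp[::-1], er[::-1], k[::-1],
                                      states[::-1], 0.1, 0.05, rev)
        assert ll_f == pytest.approx(ll_r, abs=1e-9)


class TestKalmanMarginal:
    def test_matches_analytic_gaussian_marginalisation(self):
        """Kalman-filter likelihood equals the closed-form marginal of the
        joint state-space density (states integrated out)."""
        dd = make_toy_day(m=5, seed=4)
        gpp, er, k600 = 4.0, -6.0, 12.0
        so, sp = 0.07, 0.04
        a, b = _step_coefficients(gpp, er, k600, dd.depth, dd.light_frac,
                                  dd.osat, dd.wtr, dd.dt_days)
        a, b = a[0], b[0]
        m = dd.obs.shape[1]
        # deterministic path from the pinned initial state
        det = np.empty(m)
        det[0] = dd.obs[0, 0]
        for i in range(m - 1):
            det[i + 1] = a[i] * det[i] + b[i]
        # x_i = det_i + sum_j A[i,j] eta_j ; obs = x + eps  (i >= 1)
        A = np.zeros((m - 1, m - 1))
        for i in range(1, m):
            for j in range(1, i + 1):
                A[i - 1, j - 1] = np.prod(a[j:i])
        cov = sp**2 * A @ A.T + so**2 * np.eye(m - 1)
        # the first observation's term vanishes (state pinned to obs)
        expect = multivariate_normal.logpdf(dd.obs[0, 1:], mean=det[1:], cov=cov)
        got = kalman_loglik(np.array([[gpp]]), np.array([[er]]),
                            np.array([[k600]]), np.array([so]), np.array([sp]),
                            dd)[0]
        assert got == pytest.approx(expect, abs=1e-8)

    def test_batched_evaluation_matches_loop(self):
        dd = make_toy_day(m=6, seed=5)
        rng = np.random.default_rng(0)
        B = 7
        gpp = rng.uniform(0, 8, (B, 1))
        er = rng.uniform(-10, 0, (B, 1))
        k = rng.uniform(2, 20, (B, 1))
        so = rng.uniform(0.02, 0.2, B)
        sp = rng.uniform(0.01, 0.1, B)
        batch = kalman_loglik(gpp, er, k, so, sp, dd)
        for i in range(B):
            single = kalman_loglik(gpp[i:i + 1], er[i:i + 1], k[i:i + 1],
                                   so[i:i + 1], sp[i:i + 1], dd)[0]
            assert batch[i] == pytest.approx(single, abs=1e-10)
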