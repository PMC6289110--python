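"""Shared fixtures: synthetic sites and pre-computed fits reused across tests.

MCMC-bearing fixtures are session-scoped and use small problem sizes
(4-14 days, 15-60 min resolution, shortened chains) so the whole suite runs
in minutes on one CPU.
"""

import warnings

import numpy as np
import pytest

from rivermetab import (SyntheticSiteConfig, fit_metabolism, generate_site,
                        prepare_model_input)
from rivermetab.oxygen_model import stack_days

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def default_site():
    """The default 14-day, 15-min synthetic site (seed 1)."""
    cfg = SyntheticSiteConfig(seed=1)
    raws, truth = generate_site(cfg)
    return raws, truth


@pytest.fixture(scope="session")
def default_input(default_site):
    raws, truth = default_site
    (mi,) = prepare_model_input(truth.site, raws)
    return mi


@pytest.fixture(scope="session")
def default_daydata(default_input):
    return stack_days(default_input)


@pytest.fixture(scope="session")
def small_fit():
    """A quick pooled fit on a 6-day, 30-min site, with its truth record."""
    cfg = SyntheticSiteConfig(seed=3, n_days=6, resolution_min=30)
    raws, truth = generate_site(cfg)
    (mi,) = prepare_model_input(truth.site, raws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_metabolism(mi, chains=4, warmup=400, saved=200, seed=11)
    return fit, truth


def make_toy_day(m=8, dt_days=1.0 / 96.0, seed=0):
    """A tiny single-day DayData for closed-form likelihood checks."""
    from rivermetab.oxygen_model import DayData

    rng = np.random.default_rng(seed)
    tt = np.arange(m) / m * 24.0
    ppfd = np.clip(np.sin((tt - 6.0) / 12.0 * np.pi), 0, None) * 1500.0
    return DayData(
        dates=["toy"], dt_days=dt_days,
        obs=(9.0 + 0.5 * rng.standard_normal(m))[None, :],
        depth=np.full((1, m), 0.5),
        ppfd=ppfd[None, :],
        osat=np.full((1, m), 9.1),
        wtr=np.full((1, m), 17.5),
        daily_lnq=np.array([np.log(5.0)]),
    )
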