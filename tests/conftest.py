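"""Shared fixtures: small synthetic panels, life tables and episode frames."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lifegap as lg

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator config shared by the slower fixtures."""
    return lg.SimulationConfig(n_persons=6000, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return lg.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return lg.simulate_life_tables(small_config)


@pytest.fixture(scope="session")
def small_episodes(small_panel):
    return lg.build_episodes(small_panel)


@pytest.fixture(scope="session")
def small_rr(small_episodes):
    return lg.fit_relative_risks(small_episodes)


def gompertz_makeham_qx(a, b, c, max_age, *, factor=1.0, close=False):
    """Exact one-year death probabilities of a Gompertz-Makeham hazard."""
    ages = np.arange(0, max_age + 1)
    if b > 0:
        H = c + a * (np.exp(b * (ages + 1)) - np.exp(b * ages)) / b
    else:
        H = np.full(ages.shape, c + a, dtype=float)
    q = -np.expm1(-H * factor)
    s = pd.Series(q, index=ages, name="qx")
    if close:
        s = pd.concat([s, pd.Series([1.0], index=[max_age + 1])])
        s.index.name = "age"
    return s


def toy_episode_frame(start, stop, event, group, sex="male", band="fifty_one_plus"):
    """Hand-rolled episode frame for solver-level tests."""
    n = len(start)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": sex,
            "age_start": np.asarray(start, dtype=float),
            "age_stop": np.asarray(stop, dtype=float),
            "event": np.asarray(event, dtype=bool),
            "income_group": np.asarray(group),
            "age_band": band,
            "calendar_year": 2000,
        }
    )
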