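"""Shared fixtures: expensive simulations are run once per session."""

import numpy as np
import pytest

import cardioresp as cr
from cardioresp.protocols import run_spirometry
from cardioresp.simulate import simulate


@pytest.fixture(scope="session")
def healthy():
    return cr.healthy_subject()


@pytest.fixture(scope="session")
def healthy_700(healthy):
    """Standard 700 s healthy run (500 s settling + 200 s analysis)."""
    return simulate(healthy, duration_s=700.0)


@pytest.fixture(scope="session")
def healthy_summary(healthy_700):
    return cr.tpss_summary(healthy_700, window_s=200.0)


@pytest.fixture(scope="session")
def spiro_healthy(healthy):
    return run_spirometry(healthy)


@pytest.fixture(scope="session")
def spiro_small_airways(healthy):
    s = healthy.copy()
    s.alpha = 0.205
    return run_spirometry(s)


@pytest.fixture(scope="session")
def spiro_emphysema(healthy):
    s = healthy.copy()
    s.v_unloaded = 1.05
    s.e_total = 2.75
    return run_spirometry(s)


@pytest.fixture(scope="session")
def ph_110(healthy):
    """110 s resting run with the pulmonary-hypertensive resistance."""
    s = healthy.copy()
    s.r_pa = 0.370
    return simulate(s, duration_s=110.0)


def mean_ppa_last(result, window_s=10.0):
    return float(np.mean(result.window(window_s).derived("p_pa")))
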