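import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hergkin as hk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wt():
    return hk.load_parameters("WT")


@pytest.fixture(scope="session")
def wt_rpr():
    return hk.load_parameters("WT+RPR")


@pytest.fixture(scope="session")
def r56q():
    return hk.load_parameters("R56Q")


@pytest.fixture(scope="session")
def r56q_rpr():
    return hk.load_parameters("R56Q+RPR")


@pytest.fixture
def hek_cell():
    return hk.CellConfig.hek_37C(g_kr_uS=0.0847)


@pytest.fixture
def fast_settings():
    return hk.SimulationSettings(sampling_ms=0.5)


def rate_log_errors(fitted, truth, v_range=(-120.0, 60.0)):
    """Max over voltage of |ln(rate_fitted / rate_true)| for each of the six
    transition rates (the identifiable form of per-parameter recovery)."""
    vs = np.linspace(v_range[0], v_range[1], 37)
    signs = (+1, -1, +1, -1, +1, -1)
    names = ("a1", "b1", "bh", "ah", "a2", "b2")
    out = {}
    for k, (name, s) in enumerate(zip(names, signs)):
        dlp = np.log(fitted.values[2 * k] / truth.values[2 * k])
        dsl = fitted.values[2 * k + 1] - truth.values[2 * k + 1]
        out[name] = float(np.max(np.abs(dlp + s * dsl * vs)))
    return out
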