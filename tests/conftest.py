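import numpy as np
import pytest

import bufferguts as bg


@pytest.fixture(scope="session")
def sd_params():
    return bg.TKTDParams(kd=0.5, hb=0.02, mechanism="SD", z=0.2, b_kill=2.0)


@pytest.fixture(scope="session")
def it_params():
    return bg.TKTDParams(kd=0.5, hb=0.02, mechanism="IT", alpha=0.5, beta=2.0)


@pytest.fixture(scope="session")
def contact_design():
    return bg.make_design("acute_contact", n_levels=5)


@pytest.fixture(scope="session")
def small_design():
    """Cheap design for calibration smoke tests."""
    return bg.make_design("acute_contact", n_levels=3, n_replicates=2, horizon=5.0)


@pytest.fixture(scope="session")
def sd_dataset(contact_design, sd_params):
    return bg.simulate_dataset(contact_design, "BUFFER_SD", sd_params, seed=4)


@pytest.fixture(scope="session")
def quick_settings():
    return bg.MCMCSettings(chains=2, tune=600, draws=600)


@pytest.fixture(scope="session")
def sd_result(sd_dataset, quick_settings):
    return bg.calibrate("BUFFER_SD", sd_dataset, settings=quick_settings, seed=4)


@pytest.fixture
def pulse_profile():
    ev = bg.ExposureEvent("acute_contact", 1.0, 0.0)
    return bg.discretize_events([ev])


@pytest.fixture
def chronic_profile():
    ev = bg.ExposureEvent("chronic_oral", 0.3, 0.0, 10.0)
    return bg.discretize_events([ev], horizon=10.0)


def random_params(rng, mechanism):
    kd = 10 ** rng.uniform(-1.5, 1.0)
    hb = 10 ** rng.uniform(-3, -0.7)
    if mechanism == "SD":
        return bg.TKTDParams(kd=kd, hb=hb, mechanism="SD",
                             z=10 ** rng.uniform(-2, 0.5),
                             b_kill=10 ** rng.uniform(-1, 1))
    return bg.TKTDParams(kd=kd, hb=hb, mechanism="IT",
                         alpha=10 ** rng.uniform(-1.5, 0.7),
                         beta=10 ** rng.uniform(-0.3, 0.9))


@pytest.fixture(scope="session")
def param_sampler():
    return random_params
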