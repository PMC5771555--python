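import numpy as np
import pytest

from canopyflow import CountSimParams, TurbSimParams
from canopyflow import adv_processing as adv
from canopyflow import synthetic_data as syn


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, spike-free, aligned burst parameters."""
    return TurbSimParams(
        epsilon=1e-5,
        mean_speed=0.2,
        noise_sd=0.0,
        spike_rate=0.0,
        angles=(0.0, 0.0, 0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_burst(clean_params):
    return syn.simulate_adv_burst(clean_params, elevation=38.0, location="A")


@pytest.fixture(scope="session")
def default_burst():
    """Burst under the generator's default (noisy, spiky) conditions."""
    return syn.simulate_adv_burst(TurbSimParams(seed=13), elevation=23.0, location="B")


@pytest.fixture(scope="session")
def decomposed_clean(clean_burst):
    return adv.decompose(clean_burst, cutoff=0.1)


@pytest.fixture()
def null_count_params():
    """Count-generator parameters with no effects: i.i.d. Poisson records."""
    return CountSimParams(
        beta0=float(np.log(5.0)),
        beta_pos=(0.0, 0.0, 0.0, 0.0),
        beta_tide=0.0,
        phi_ar=0.0,
        sigma_ar=0.0,
        dispersion=1.0,
        gamma0=0.0,
        gamma_pos=(0.0, 0.0, 0.0, 0.0),
        gamma_tide=0.0,
        seed=101,
    )
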