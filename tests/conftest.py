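import numpy as np
import pytest

from edemarec import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_case():
    """One default phantom, shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        adc_background_sd=0.0, adc_tumor_sd=0.0, adc_edema_sd=0.0,
        adc_infil_sd=0.0, infil_outlier_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_case(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
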