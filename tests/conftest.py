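import numpy as np
import pytest

from neuroflux.config import RunConfig
from neuroflux import synthdata as sd


@pytest.fixture(scope="session")
def clean_subject():
    """Noiseless, eddy-free rendered subject with exactly coupled CSF."""
    return sd.make_subject(sd.SubjectProfile(csf_noise_frac=0.0), seed=3, grid=64)


@pytest.fixture(scope="session")
def clean_config():
    return RunConfig(noise_sd_mm_s=0.0, eddy_gradient=(0.0, 0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
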