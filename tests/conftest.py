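import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "kerafam",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kerafam")


@pytest.fixture
def family1():
    from kerafam import datasets

    return datasets.family1_pedigree()


@pytest.fixture
def family2():
    from kerafam import datasets

    return datasets.family2_pedigree()


@pytest.fixture
def ppip5k2():
    from kerafam.transcripts import synthetic_ppip5k2_transcript

    return synthetic_ppip5k2_transcript()


@pytest.fixture
def rng():
    return np.random.default_rng(20190518)
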