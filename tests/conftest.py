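import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bank():
    """A compact filter bank (6-s segments at 100 Hz) for fast unit tests."""
    from apneawst.scattering import build_filter_bank
    return build_filter_bank(fs=100.0, T=6.0, signal_len=600)


@pytest.fixture(scope="session")
def full_bank():
    """The study-scale filter bank: 60-s segments at 100 Hz, Q1=8, Q2=1."""
    from apneawst.scattering import build_filter_bank
    return build_filter_bank(fs=100.0, T=60.0, Q1=8, Q2=1, signal_len=6000)


@pytest.fixture(scope="session")
def mixed_record():
    """A 10-minute synthetic record with both classes."""
    from apneawst.synthetic import SynthConfig, generate_record
    return generate_record(SynthConfig(n_minutes_normal=5, n_minutes_apnea=5,
                                       seed=42))
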