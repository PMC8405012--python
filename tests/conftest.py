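import numpy as np
import pytest

from hrnv.sequences import RriSequence
from hrnv.synthetic import TachogramSpec, generate_rri


@pytest.fixture(scope="session")
def modulated_rri() -> RriSequence:
    """Five-minute tachogram with both oscillatory components and noise."""
    spec = TachogramSpec(
        duration_s=300.0, mean_hr=70.0, lf_freq=0.1, hf_freq=0.25,
        lf_amp=0.05, hf_amp=0.05, noise_sd=5.0, seed=1,
    )
    return generate_rri(spec)


@pytest.fixture(scope="session")
def metronomic_rri() -> RriSequence:
    return generate_rri(TachogramSpec(duration_s=300.0, mean_hr=60.0, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_tachogram(seed: int, duration_s: float = 300.0) -> RriSequence:
    """Helper for multi-seed property tests."""
    return generate_rri(
        TachogramSpec(
            duration_s=duration_s, mean_hr=75.0, lf_amp=0.04, hf_amp=0.04,
            noise_sd=8.0, seed=seed,
        )
    )
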