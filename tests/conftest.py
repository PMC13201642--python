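import numpy as np
import pytest

from wmhkit import phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Small noisy phantom shared by read-only tests."""
    return phantom.make_phantom(phantom.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def separable_phantom_pair():
    """(zero-noise input phantom, noisy calibration phantom) with large
    confluent lesions and well-separated class means."""
    kwargs = dict(
        seed=2,
        bias_amplitude=0.0,
        n_punctate=0,
        n_confluent=3,
        lesion_radius_range=(5.5, 7.0),
    )
    clean = phantom.make_phantom(phantom.PhantomConfig(noise_sd=0.0, **kwargs))
    calib = phantom.make_phantom(phantom.PhantomConfig(noise_sd=1.0, **kwargs))
    return clean, calib


@pytest.fixture
def rng():
    return np.random.default_rng(42)
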