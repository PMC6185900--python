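import math

import numpy as np
import pytest

from cellwater import DecaySimSpec, MultiExpModel, generate_decay


@pytest.fixture
def fresh_model() -> MultiExpModel:
    """Bi-exponential decomposition of fresh (undried) apple tissue:
    88.10% at T2 90.67 ms (ICW) and 11.97% at 32.76 ms (FW)."""
    return MultiExpModel.from_arrays([88.10, 11.97], [90.67, 32.76])


@pytest.fixture
def noiseless_curve(fresh_model):
    """1000-echo, 10-ms-spacing noiseless decay from the fresh-tissue model."""
    return generate_decay(DecaySimSpec(model=fresh_model, snr=math.inf))


def make_noisy_curve(model, snr, seed, noise_model="gaussian", **kwargs):
    return generate_decay(
        DecaySimSpec(model=model, snr=snr, noise_model=noise_model, seed=seed, **kwargs)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
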