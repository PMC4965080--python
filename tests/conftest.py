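import numpy as np
import pytest

from dkihist import BValueScheme, DKIParams, dki_signal


@pytest.fixture
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture
def normal_params() -> DKIParams:
    """Normal peripheral-zone median operating point."""
    return DKIParams(s0=100.0, d_app=2.07e-3, k_app=0.59)


@pytest.fixture
def tumor_params() -> DKIParams:
    """Tumor median operating point."""
    return DKIParams(s0=100.0, d_app=1.53e-3, k_app=0.75)


def forward_signals(scheme: BValueScheme, params: DKIParams) -> np.ndarray:
    """Noise-free forward signals used as fit oracles."""
    return dki_signal(scheme.as_array, params)


def rician_sample(rng, clean, sigma, size=None):
    """Rician magnitudes |(S + e1) + i e2| with per-channel noise sigma."""
    shape = np.shape(clean) if size is None else size
    e1 = rng.normal(0.0, sigma, shape)
    e2 = rng.normal(0.0, sigma, shape)
    return np.hypot(np.asarray(clean) + e1, e2)
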