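import numpy as np
import pytest

from semfocus import FramePair


@pytest.fixture
def gaussian_pair():
    """Factory for registered pairs with known signal/noise sd.

    The shared component is i.i.d. Gaussian with sd ``signal_sd``; each
    frame adds independent Gaussian noise with sd ``noise_sd`` -- the
    exact statistical model behind the covariance SNR estimator, with
    true SNR = signal_sd / noise_sd.
    """

    def make(signal_sd, noise_sd, shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        s = rng.normal(0.0, signal_sd, shape) if signal_sd > 0 else np.zeros(shape)
        a = s + rng.normal(0.0, noise_sd, shape)
        b = s + rng.normal(0.0, noise_sd, shape)
        return FramePair.from_arrays(a, b)

    return make
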