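import numpy as np
import pytest

from veinmotion import FrameSequence, GrayFrame, make_speckle


@pytest.fixture(scope="session")
def speckle_frame() -> GrayFrame:
    """A 160x160 seeded speckle texture shared across read-only tests."""
    return make_speckle(160, 160, density=0.01, radius=2.0, seed=7)


@pytest.fixture()
def identical_pair(speckle_frame) -> FrameSequence:
    """Two identical frames: the no-motion case."""
    return FrameSequence(
        [
            GrayFrame(speckle_frame.pixels.copy(), 0),
            GrayFrame(speckle_frame.pixels.copy(), 1),
        ],
        fps=30.0,
    )


def fourier_translate(pixels: np.ndarray, u: float, v: float) -> np.ndarray:
    """Band-limited translation of a (periodic) image by (u, v) pixels.

    Content moves toward larger x by u and larger y by v, matching the DIC
    sign convention: the shifted image equals the original sampled at
    (x - u, y - v).
    """
    from scipy.ndimage import fourier_shift

    return np.fft.ifft2(fourier_shift(np.fft.fft2(pixels), (v, u))).real
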