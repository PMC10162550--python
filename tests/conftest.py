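import numpy as np
import pytest
from scipy import ndimage

from retppg.synthetic import SceneParams, generate_cohort, generate_eye_video


@pytest.fixture(scope="session")
def default_cohort():
    """Default planted cohort (111 eyes, fast mode), seed 0."""
    return generate_cohort(seed=0)


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random texture, useful as a registration target."""
    rng = np.random.default_rng(42)
    img = ndimage.gaussian_filter(rng.random((128, 128)), 3.0)
    return (img - img.min()) / np.ptp(img)


@pytest.fixture(scope="session")
def still_noiseless_stack():
    """Noiseless, motion-free video with uniform planted amplitude 0.03."""
    params = SceneParams(
        height=128,
        width=128,
        amplitude_map=np.full((128, 128), 0.03),
        noise_sigma=0.0,
        motion_max_shift=0.0,
        motion_max_rot=0.0,
    )
    return generate_eye_video(params, seed=1)


def fourier_shift(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Subpixel circular shift via the Fourier shift theorem (test oracle)."""
    f = np.fft.fft2(image)
    ky = np.fft.fftfreq(image.shape[0])[:, None]
    kx = np.fft.fftfreq(image.shape[1])[None, :]
    return np.real(np.fft.ifft2(f * np.exp(-2j * np.pi * (ky * dy + kx * dx))))
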