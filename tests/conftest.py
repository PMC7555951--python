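import numpy as np
import pytest

import focitrack as ft


def make_two_spot_image(sep: float = 5.0, sigma: float = 2.0, amp: float = 100.0,
                        bg: float = 10.0, size: int = 40):
    """Two Gaussian spots on a flat background, merged at moderate thresholds."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size // 2
    cx1 = size // 2 - int(round(sep / 2))
    cx2 = cx1 + int(round(sep))
    img = bg + amp * (
        np.exp(-((xx - cx1) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        + np.exp(-((xx - cx2) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    )
    return img, [(cx1, cy), (cx2, cy)]


@pytest.fixture(scope="session")
def two_spot_image():
    return make_two_spot_image()


@pytest.fixture(scope="session")
def clean_timelapse():
    """Noise-free drift-free stack with 6 slowly diffusing foci plus its truth."""
    cfg = ft.SimConfig(
        image_size=(160, 160),
        n_frames=10,
        nucleus_center=(80.0, 80.0),
        nucleus_axes=(58.0, 46.0),
        n_initial_foci=6,
        birth_rate=0.0,
        death_prob=0.0,
        diffusion_coefficient=0.001,
        amplitude_growth=0.0,
        bleach_rate=0.0,
        noise_poisson_scale=0.0,
        noise_gaussian_sd=0.0,
        seed=5,
    )
    stack, truth = ft.simulate_timelapse(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def coloc_field():
    """1000 channel-A foci (200 nuclei x 5) with nested-count truth."""
    return ft.simulate_two_channel(
        n_cells=200,
        foci_per_cell=5,
        nested_counts_distribution={0: 0.6, 1: 0.3, 2: 0.1},
        edu_positive_fraction=1.0,
        seed=11,
    )
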