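import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from speckleflow.synthetic import SimulationConfig, generate_static_speckle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def static_frame():
    """One noise-free 512x512 fully developed speckle frame, grain 6 px."""
    config = SimulationConfig(image_shape=(512, 512), grain_size_px=6.0, seed=7)
    return generate_static_speckle(config)


@pytest.fixture(scope="session")
def small_frame():
    """A 64x64 speckle crop for brute-force oracle comparisons."""
    config = SimulationConfig(image_shape=(64, 64), grain_size_px=4.0, seed=11)
    return generate_static_speckle(config)


def brute_force_autocovariance(img: np.ndarray) -> np.ndarray:
    """O(N^2) shift-and-multiply normalized linear autocovariance.

    Independent oracle for the FFT (Wiener-Khinchin) route: for every lag
    (dr, dc) the mean-subtracted products are summed over the overlap
    region, divided by the overlap count, and the map is normalized by its
    zero-lag value.
    """
    img = np.asarray(img, float)
    centered = img - img.mean()
    n, m = img.shape
    out = np.zeros((2 * n - 1, 2 * m - 1))
    for dr in range(-(n - 1), n):
        for dc in range(-(m - 1), m):
            r0, r1 = max(0, -dr), n - max(0, dr)
            c0, c1 = max(0, -dc), m - max(0, dc)
            a = centered[r0:r1, c0:c1]
            b = centered[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            out[dr + n - 1, dc + m - 1] = (a * b).mean()
    return out / out[n - 1, m - 1]
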