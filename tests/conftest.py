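import numpy as np
import pytest

from greenhia import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_bundle():
    """Contaminated study: clouds, water, outliers, scene noise."""
    return generate_study(SyntheticConfig(n_cities=8, grid_size=16, seed=42))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Clean study: exposures must reproduce the ground truth exactly."""
    return generate_study(
        SyntheticConfig(
            n_cities=10, grid_size=16, noise_sd=0.0, cloud_rate=0.0,
            outlier_rate=0.0, seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def ray_casting_contains(polygon, x, y):
    """Independent even-odd point-in-polygon test on the exterior ring."""
    coords = list(polygon.exterior.coords)
    inside = False
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
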