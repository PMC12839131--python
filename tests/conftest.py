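import numpy as np
import pytest

from spheromet.synthgen import DoseScenario, ImageSpec, make_dose_tables, make_spheroid_image


@pytest.fixture(scope="session")
def clean_disc():
    """Noiseless disc frame, radius 50."""
    return make_spheroid_image(ImageSpec(radius=50, seed=1))


@pytest.fixture(scope="session")
def noiseless_tables():
    """Deterministic dose tables (no noise, no outliers)."""
    return make_dose_tables(DoseScenario(noise_cv=0, outlier_rate=0, seed=0))


@pytest.fixture(scope="session")
def noisy_tables():
    """Default study-condition tables (10% CV, no outliers)."""
    return make_dose_tables(DoseScenario(noise_cv=10, outlier_rate=0, seed=11))


def random_blob_mask(seed: int, size: int = 64) -> np.ndarray:
    """Star-convex random blob mask for oracle-equivalence fixtures."""
    rng = np.random.default_rng(seed)
    n = size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    base = n * 0.3
    modes = rng.integers(2, 6, size=3)
    amps = rng.uniform(0.05, 0.2, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    r = base * (1 + sum(a * np.sin(m * theta + p) for a, m, p in zip(amps, modes, phases)))
    return rad <= r
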