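import numpy as np
import pytest

from nirtransfer import SpectralDataset, default_four_brand_study, default_grid

BRANDS = ("#1", "#2", "#3", "#4")


def make_dataset(n=5, d=8, seed=0, brand="#1"):
    """Small random-but-valid dataset for I/O and plumbing tests."""
    rng = np.random.default_rng(seed)
    grid = default_grid(10_000, 4_000, (10_000 - 4_000) / (d - 1)) if d > 1 else np.array([5000.0])
    return SpectralDataset(
        wavenumbers=grid[:d],
        absorbance=rng.uniform(0.1, 1.2, size=(n, d)),
        target=rng.uniform(0, 100, size=n),
        brand=np.array([brand] * n, dtype=object),
        sample_id=np.array([f"{brand}-{i:03d}" for i in range(n)], dtype=object),
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def five_seed_studies():
    """Default four-brand studies for seeds 1..5 (shared by the slow tests)."""
    return {seed: default_four_brand_study(seed) for seed in range(1, 6)}


@pytest.fixture(scope="session")
def default_study(five_seed_studies):
    return five_seed_studies[1]
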