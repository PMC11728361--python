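from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from echotex.pipeline import extract_features_table
from echotex.synthetic import SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Factory for random uint8 test images."""

    def make(rows: int = 8, cols: int = 8, levels: int = 256) -> np.ndarray:
        return rng.integers(0, levels, size=(rows, cols), dtype=np.uint8)

    return make


@pytest.fixture(scope="session")
def default_cohort():
    """The default 130-image graded cohort (seed 42), generated once."""
    config = SyntheticCohortConfig()
    images, records, truths = generate_cohort(config)
    return config, images, records, truths


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Full 21-feature table of the default cohort, extracted once."""
    _, images, records, _ = default_cohort
    return extract_features_table(images, records)


@pytest.fixture
def small_config():
    """Smoke-scale cohort: 5 images per grade, 64x64."""
    from dataclasses import replace

    profiles = tuple(replace(p, n=5) for p in SyntheticCohortConfig().profiles)
    return SyntheticCohortConfig(profiles=profiles, image_size=(64, 64), seed=7)
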