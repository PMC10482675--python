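from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from soundscape import (
    AnalysisConfig,
    FeatureMapConfig,
    LandscapeConfig,
    PointCount,
    generate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_LANDSCAPE = LandscapeConfig(
    n_sites=6, n_species=30, n_point_counts=60, seed=11
)
SMALL_MAP = FeatureMapConfig(n_lf=16, n_ssi=4, map_seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    return generate_dataset(SMALL_LANDSCAPE, SMALL_MAP, dataset_id="toy")


@pytest.fixture(scope="session")
def small_config():
    return AnalysisConfig(seed=3, mantel_permutations=199)


def make_point_count(pc_id="pc0", species=(), site="s0", dataset="d0",
                     start=datetime(2021, 5, 1, 8, 0), duration=20.0):
    return PointCount(
        id=pc_id, dataset_id=dataset, site_id=site, start_time=start,
        duration=duration, species=frozenset(species),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
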