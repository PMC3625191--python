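import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fcmvpa as f

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Small strongly-separated cohort (10+10 subjects, 15 regions,
    5 planted reductions) used by pipeline-level tests."""
    spec = f.SimSpec(
        n_pos=10,
        n_neg=10,
        n_regions=15,
        n_timepoints=256,
        n_networks=3,
        r_within=0.6,
        r_between=0.4,
        n_planted=5,
        delta_r=0.4,
        seed=7,
    )
    return f.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    X, y, idx = f.cohort_features(small_cohort)
    return X, y, idx


@pytest.fixture(scope="session")
def null_cohort_features():
    """Exchangeable two-group cohort with no planted effect."""
    spec = f.SimSpec(
        n_pos=12,
        n_neg=12,
        n_regions=12,
        n_timepoints=128,
        n_networks=3,
        n_planted=0,
        delta_r=0.0,
        seed=11,
    )
    cohort = f.simulate_cohort(spec)
    X, y, idx = f.cohort_features(cohort)
    return cohort, X, y, idx


@pytest.fixture()
def tiny_atlas():
    return f.AtlasTable(
        region_names=("RegA", "RegB", "RegC", "RegD"),
        network_ids=np.array([1, 1, 2, 2]),
        network_names=("NetOne", "NetTwo"),
    )
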