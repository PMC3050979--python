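import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cllmir as cm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (38 CLL / 9 control / 5 activated,
    planted activation signature, survival outcomes)."""
    cfg = cm.CohortConfig(seed=1)
    matrix, table, truth = cm.generate_cohort(cfg)
    table = cm.generate_survival(cfg, truth, table, matrix)
    return cfg, matrix, table, truth


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    cfg, matrix, table, truth = default_cohort
    norm, provenance = cm.normalize_matrix(matrix)
    return cfg, norm, table, truth, provenance


def null_cohort_config(seed, n_features=50, **kwargs):
    """A cohort with no planted effects (shared helper)."""
    defaults = dict(
        feature_names=[f"miR-null-{i}" for i in range(n_features)],
        planted_up={},
        planted_down={},
        prognostic_features={},
        high_background_features=frozenset(),
        seed=seed,
    )
    defaults.update(kwargs)
    return cm.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110308)
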