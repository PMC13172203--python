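import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    from ggnfusion import SimConfig, generate_cohort

    cfg = SimConfig(n_patients=120, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from ggnfusion.cohortsim import simulate_feature_table

    cfg, cohort = small_cohort
    return simulate_feature_table(cohort, cfg)


@pytest.fixture(scope="session")
def sphere_scan():
    """Synthetic 1-mm sphere phantom, radius 5 mm, constant -600 HU."""
    from ggnfusion.radiomics import NoduleScan

    shape = (21, 21, 21)
    c = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).astype(float)
    r2 = sum((idx[k] - c[k]) ** 2 for k in range(3))
    mask = r2 <= 5.0**2
    grid = np.full(shape, -1000.0)
    grid[mask] = -600.0
    return NoduleScan(grid, mask, (1.0, 1.0, 1.0))
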