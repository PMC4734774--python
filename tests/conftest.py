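import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neutralclone as nc
from neutralclone.simulate import SimulationConfig, ensemble

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ENSEMBLE_SEED = 20160201


@pytest.fixture(scope="session")
def params_072():
    return nc.BranchingParams(b=0.25, d=0.18, u=0.015)


@pytest.fixture(scope="session")
def params_099():
    return nc.BranchingParams.from_delta(0.99, u=0.015)


@pytest.fixture(scope="session")
def ensemble_072(params_072):
    """2,000 surviving runs at delta=0.72 to 5e4 cells, conditioned on at
    least three successful mutations (shared by CDF, fixation and tree
    checks; ~1 min with the jitted kernel)."""
    return ensemble(
        params_072,
        SimulationConfig(stop_size=50_000, required_successful=3),
        2_000,
        seed=ENSEMBLE_SEED,
    )


@pytest.fixture(scope="session")
def ensemble_099(params_099):
    """2,000 surviving runs at delta=0.99 to 5e3 cells (the expensive
    regime: ~1e6 events per surviving run)."""
    return ensemble(
        params_099,
        SimulationConfig(stop_size=5_000, required_successful=3),
        2_000,
        seed=ENSEMBLE_SEED,
    )


def ks_distance(result, k, params, npoints=400):
    """Sup-distance between the ensemble's empirical eventual-frequency CDF
    and the analytic law for the k-th successful mutation."""
    grid = np.linspace(0.001, 0.999, npoints)
    emp = np.array([result.ecdf(k)(a) for a in grid])
    return float(np.max(np.abs(emp - nc.frequency_cdf(k, grid, params))))
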