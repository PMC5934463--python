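import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vforg as v

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout40():
    return v.generate_layout(40, seed=1)


@pytest.fixture(scope="session")
def two_cluster():
    """Small two-cluster ensemble (12 channels, 6 s) with its ground truth
    and the correlation matrix at a 100 ms cycle lag window."""
    layout = v.generate_layout(12, seed=3)
    ensemble, truth = v.generate_clustered_ensemble(
        layout, k_clusters=2, df_per_cluster=[5.0, 9.0],
        within_coupling=0.95, between_coupling=0.0,
        noise_sd=0.1, drift_amplitude=0.0,
        duration_s=6.0, fs=1000.0, seed=7,
    )
    lag = v.lag_window_from_cycle_length(100.0, 1000.0)
    R = v.correlation_matrix(ensemble, lag)
    return layout, ensemble, truth, R


def random_correlation_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid symmetric correlation-like matrix (unit diagonal,
    entries in [-1, 1])."""
    M = rng.uniform(-1.0, 1.0, size=(n, n))
    R = (M + M.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R
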