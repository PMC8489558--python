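import numpy as np
import pytest

import synconn as sc


@pytest.fixture(scope="session")
def two_cluster_features():
    """Hand-computable two-cluster geometry: {(0,0),(0,1)} and {(10,0),(10,1)}."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    labels = np.array(["a", "a", "b", "b"])
    return X, labels


@pytest.fixture(scope="session")
def default_session():
    """One default ramp-and-hold session shared by read-only tests."""
    assembly, modulation, tuning = sc.default_configs(seed=11)
    trains, events, meta, gt = sc.generate_session(
        assembly, modulation, tuning, seed=11
    )
    return trains, events, meta, gt


@pytest.fixture(scope="session")
def default_metrics(default_session):
    trains, events, meta, gt = default_session
    windows = sc.make_state_windows(events)
    metrics = sc.pair_metrics(trains, windows, skip_ccg_below_r=0.2)
    return metrics


def poisson_train(rate_hz, duration_s, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0, duration_s, n))
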