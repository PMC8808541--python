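import numpy as np
import pandas as pd
import pytest

from methylaging.synthetic import TrajectorySpec, generate_beta_matrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample uniform-age cohort used by several stage tests."""
    return generate_cohort(200, 0, 100, seed=11)


@pytest.fixture(scope="session")
def noiseless_matrix(small_cohort):
    """Zero-noise matrix with one marker per trajectory family."""
    specs = [
        TrajectorySpec("const", "constant", baseline=0.3),
        TrajectorySpec("lin", "linear", baseline=0.1, slope=0.002),
        TrajectorySpec("sig", "sigmoid", baseline=0.1, amplitude=0.4, midpoint_age=50, steepness=0.2),
        TrajectorySpec("step", "step", baseline=0.2, amplitude=0.3, midpoint_age=60),
    ]
    matrix, truth = generate_beta_matrix(small_cohort, specs, seed=12)
    return matrix, truth, small_cohort


@pytest.fixture()
def toy_matrix():
    """Tiny hand-checkable probes x samples table."""
    return pd.DataFrame(
        {
            "s1": [0.1, 0.5, 0.9, 0.2],
            "s2": [0.2, 0.4, 0.8, 0.3],
            "s3": [0.3, 0.6, 0.7, 0.1],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
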