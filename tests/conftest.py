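import numpy as np
import pytest

from carposort.pipeline import ExperimentConfig, run_experiment
from carposort.synthetic_seeds import (
    DEFAULT_VARIETIES,
    default_deformation_model,
    generate_fresh_cloud,
)


@pytest.fixture(scope="session")
def deformation_model():
    return default_deformation_model()


@pytest.fixture(scope="session")
def cab_shape():
    return DEFAULT_VARIETIES["cabernet_sauvignon"]


@pytest.fixture(scope="session")
def tzu_shape():
    return DEFAULT_VARIETIES["tzuriman"]


@pytest.fixture(scope="session")
def fresh_cab_cloud(cab_shape):
    return generate_fresh_cloud(cab_shape, 3000, rng_seed=1)


@pytest.fixture(scope="session")
def experiment_report():
    """One full experiment run shared by the pipeline-level checks.

    Five-variety reference library (10 seeds each, 300-point clouds), train
    at 200 °C/2 h, Cabernet-like tests at 200/250/300 °C, 25 tournament
    sessions, plus a 100-seed unknown-provenance set split 54:46 between
    mild (≤ 250 °C) and drastic (≥ 300 °C) charring.
    """
    return run_experiment(ExperimentConfig(n_unknown_seeds=100, rng_seed=0))


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q
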