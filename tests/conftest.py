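import numpy as np
import pytest

from copulagc import JointModel, SimConfig, simulate_mixed


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_model_p2():
    """Order-2 model with no cross-coupling and no instantaneous dependence."""
    return JointModel(
        p=2, c_y=0.0, a=[0.4, -0.2], b=[0.0, 0.0], sigma=1.0,
        c_x=-1.2, d=[0.2, -0.1], e=[0.0, 0.0], rho=0.0,
    )


@pytest.fixture
def coupled_model_p2():
    """Order-2 model with spike->LFP coupling, LFP->spike coupling and rho."""
    return JointModel(
        p=2, c_y=0.1, a=[0.5, -0.3], b=[0.4, 0.2], sigma=1.0,
        c_x=-1.2, d=[0.3, -0.2], e=[0.3, 0.15], rho=0.3,
    )


@pytest.fixture
def small_trialset(null_model_p2):
    """A small simulated TrialSet (8 trials x 60 bins)."""
    return simulate_mixed(
        SimConfig(model=null_model_p2, n_trials=8, n_bins=60, seed=7)
    )


@pytest.fixture
def tiny_trialset(coupled_model_p2):
    """Tiny instance for brute-force oracle comparisons (2 trials x 8 bins)."""
    return simulate_mixed(
        SimConfig(model=coupled_model_p2, n_trials=2, n_bins=8, seed=11)
    )


def random_valid_model(rng, p=2):
    """A random JointModel draw within the documented validity region."""
    return JointModel(
        p=p,
        c_y=rng.uniform(-1, 1),
        a=rng.uniform(-0.5, 0.5, p),
        b=rng.uniform(-1, 1, p),
        sigma=rng.uniform(0.5, 2.0),
        c_x=rng.uniform(-1, 1),
        d=rng.uniform(-1, 1, p),
        e=rng.uniform(-1, 1, p),
        rho=rng.uniform(-0.9, 0.9),
    )
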