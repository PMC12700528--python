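"""Shared fixtures: small connectomes and a toy linear-Gaussian SBI problem."""

import numpy as np
import pytest

from braininv.connectome import generate_synthetic_connectome, normalize_connectome
from braininv.flows import ConditionalMAF, TrainConfig, train_flow
from braininv.inference import PriorSpec


@pytest.fixture(scope="session")
def sc5():
    """Small normalized connectome with distances (5 regions, fully connected)."""
    return normalize_connectome(generate_synthetic_connectome(5, 1.0, seed=42))


@pytest.fixture(scope="session")
def sc20():
    return normalize_connectome(generate_synthetic_connectome(20, 0.6, seed=42))


@pytest.fixture(scope="session")
def toy_problem():
    """Linear-Gaussian toy simulator with a conjugate analytic posterior.

    theta ~ U(-2, 2)^2, x = theta + eps with eps ~ N(0, 0.5^2 I). For a given
    x_obs the true posterior is N(x_obs, 0.25 I) truncated to the prior box
    (truncation negligible in the interior).
    """
    rng = np.random.default_rng(7)
    prior = PriorSpec(("a", "b"), [-2.0, -2.0], [2.0, 2.0])
    theta = rng.uniform(-2, 2, size=(8000, 2))
    x = theta + rng.normal(0, 0.5, size=theta.shape)
    return {"prior": prior, "theta": theta, "x": x, "noise_sd": 0.5}


@pytest.fixture(scope="session")
def toy_flow(toy_problem):
    """MAF trained once on the toy problem (reused across tests)."""
    flow = ConditionalMAF(d=2, m_context=2, n_transforms=5, hidden=50, seed=0)
    th, x = toy_problem["theta"], toy_problem["x"]
    flow.set_standardization(th.mean(0), th.std(0))
    train_flow(flow, th, x, TrainConfig(seed=1, max_epochs=500, patience=60,
                                        learning_rate=5e-4))
    return flow
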