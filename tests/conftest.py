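import numpy as np
import pytest

from gnnddi import (
    DDIModel,
    EncoderConfig,
    build_graph,
    build_graph_table,
    init_encoder_params,
)
from gnnddi.synthetic import benchmark_suite


@pytest.fixture(scope="session")
def molecules():
    """Small fixture molecules keyed by name."""
    return {
        "methane": build_graph("methane", "C"),
        "ethane": build_graph("ethane", "CC"),
        "benzene": build_graph("benzene", "c1ccccc1"),
        "acetic_acid": build_graph("acetic_acid", "OC(=O)C"),
        "hydroquinone": build_graph("hydroquinone", "Oc1ccc(O)cc1"),
        "propane": build_graph("propane", "CCC"),
    }


@pytest.fixture(scope="session")
def default_config():
    return EncoderConfig(seed=11)


@pytest.fixture(scope="session")
def default_params(default_config):
    return init_encoder_params(default_config)


@pytest.fixture(scope="session")
def tiny_config():
    """A deliberately small encoder for oracle and gradient tests."""
    return EncoderConfig(num_layers=2, heads=2, head_dim=3, seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return DDIModel.initialize(encoder_config=tiny_config, hidden=(5, 4, 3),
                               seed=5)


@pytest.fixture(scope="session")
def quick_bundle():
    return benchmark_suite("quick")


@pytest.fixture(scope="session")
def quick_graphs(quick_bundle):
    return build_graph_table(quick_bundle.library)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x (same shape as x)."""
    grad = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return grad
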