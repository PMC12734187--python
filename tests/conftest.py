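import numpy as np
import pytest

from mdignn.core_io import GeneGraph, RunConfig
from mdignn.synthetic_data import SimSpec, simulate_benchmark, simulate_graph


@pytest.fixture
def two_node_graph() -> GeneGraph:
    """Single directed edge A -> B."""
    return GeneGraph(nodes=("A", "B"), edges=((0, 1, 1.0, frozenset(["t"])),))


@pytest.fixture
def small_spec() -> SimSpec:
    return SimSpec(n_genes=60, n_drivers=8, n_nondrivers=20,
                   n_cancer_types=2, samples_per_type=10, seed=7)


@pytest.fixture
def small_graph(small_spec) -> GeneGraph:
    return simulate_graph(small_spec)


@pytest.fixture
def small_benchmark(small_spec):
    return simulate_benchmark(small_spec)


@pytest.fixture
def fast_config() -> RunConfig:
    """Short training schedule for unit tests (not the published defaults)."""
    return RunConfig(max_epochs=60, patience=20, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
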