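import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fcnet.net_build import BinaryNetwork, SparsityGrid, ZConnectivity
from fcnet.synthetic_data import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20150902)


@pytest.fixture
def default_grid():
    return SparsityGrid()


@pytest.fixture
def random_z(rng):
    """Factory: random symmetric z matrix with zero diagonal."""

    def make(n: int = 10) -> ZConnectivity:
        r = rng.uniform(-0.9, 0.9, size=(n, n))
        z = np.arctanh((r + r.T) / 2)
        np.fill_diagonal(z, 0.0)
        return ZConnectivity(z=z)

    return make


@pytest.fixture
def net_factory():
    def make(adj) -> BinaryNetwork:
        adj = np.asarray(adj, dtype=np.uint8)
        n = adj.shape[0]
        s = adj.sum() / max(n * (n - 1), 1)
        return BinaryNetwork(adjacency=adj, sparsity=float(min(max(s, 1e-6), 1 - 1e-6)))

    return make


@pytest.fixture
def small_spec():
    """A scaled-down cohort for fast end-to-end tests: 5+6 subjects,
    30 regions, 120 time points, same modular design as the default."""
    return CohortSpec(
        n_patients=5,
        n_controls=6,
        n_regions=30,
        n_timepoints=120,
        module_sizes_control=[6, 6, 6, 6, 6],
        module_sizes_patient=[6, 6, 6, 12],
        hub_regions=[0, 6, 12, 18, 24],
        seed=7,
    )


def path_graph(n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


def star_graph(n_leaves: int) -> np.ndarray:
    adj = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    adj[0, 1:] = adj[1:, 0] = 1
    return adj


def complete_graph(n: int) -> np.ndarray:
    adj = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(adj, 0)
    return adj
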