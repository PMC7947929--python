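import numpy as np
import pytest

from gmsimnet import GMVolume, SimulationConfig
from gmsimnet.synthetic import generate_atlas, generate_subject_volume


@pytest.fixture(scope="session")
def small_atlas():
    """8-parcel atlas on a 12^3 grid (fully labeled)."""
    return generate_atlas((12, 12, 12), 8, seed=0)


@pytest.fixture(scope="session")
def desk_atlas():
    """90-parcel atlas on the 24^3 desk-scale grid."""
    return generate_atlas((24, 24, 24), 90, seed=1)


@pytest.fixture
def noise_volume(small_atlas):
    """Pure-noise volume on the small atlas grid."""
    cfg = SimulationConfig(n_per_group=2, grid_shape=(12, 12, 12), n_rois=8,
                           signal_amplitude=0.0)
    rng = np.random.default_rng(99)
    return generate_subject_volume(small_atlas, "HC", cfg, rng)


@pytest.fixture
def cube_volume():
    """Fully-masked unit-voxel volume of iid noise, 30^3 (1000 cubes)."""
    rng = np.random.default_rng(7)
    return GMVolume(rng.normal(10.0, 1.0, (30, 30, 30)), (1.0, 1.0, 1.0),
                    mask=np.ones((30, 30, 30), dtype=bool))


def graphs_for_oracles():
    """All connected non-isomorphic graphs with n<=6 plus 200 random n<=10."""
    import networkx as nx

    graphs = []
    for g in nx.graph_atlas_g()[1:]:
        if g.number_of_nodes() <= 6 and g.number_of_nodes() >= 2 \
                and nx.is_connected(g):
            graphs.append(nx.to_numpy_array(g) > 0)
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(2, 11))
        p = float(rng.uniform(0.2, 0.9))
        a = rng.random((n, n)) < p
        a = np.triu(a, 1)
        a = a | a.T
        graphs.append(a)
    return graphs
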