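import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-scale network used by fast end-to-end tests."""
    from msbnet.network import NetworkSpec

    return NetworkSpec(sim_duration=3.0, analysis_window=2.0)


@pytest.fixture(scope="session")
def synth_table():
    """Default synthetic synapse table (200 boutons, within SD < between SD)."""
    from msbnet.synthetic import SynapseGenParams, generate_synapse_table

    return generate_synapse_table(SynapseGenParams(seed=3))


@pytest.fixture(scope="session")
def parallel_branch_tree():
    """Toy arbor: two straight branches running parallel 3 um apart.

    Branch A runs from the soma along +x at y = 0; branch B jogs from the
    soma to (0, 3, 0) and then runs along +x at y = 3.  Analytic geometry:
    every node past the proximal region has exactly one separate branch
    within 5 um (Euclidean gap 3 um) and none within 2 um.
    """
    from msbnet.morphometrics import NeuriteTree

    n = 60
    xs = np.arange(1, n + 1) * 0.5
    xyz_a = np.column_stack([xs, np.zeros(n), np.zeros(n)])
    xyz_b = np.column_stack([xs, np.full(n, 3.0), np.zeros(n)])
    xyz = np.vstack([[0.0, 0.0, 0.0], xyz_a, [[0.0, 3.0, 0.0]], xyz_b])
    parent = np.concatenate([
        [-1],
        [0] + list(range(1, n)),
        [0],
        [n + 1] + list(range(n + 2, n + 1 + n)),
    ])
    return NeuriteTree(xyz=xyz.astype(float), parent=parent.astype(int))
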