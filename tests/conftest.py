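import numpy as np
import pytest

from dynmesh import preprocessing as prep
from dynmesh import synthetic_data as synth
from dynmesh.network_metrics import PreparedNetwork, _length_matrix


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 2 subjects x 1 run, 10 puzzles, 12 regions."""
    return synth.SyntheticConfig(
        n_subjects=2, n_runs=1, n_puzzles_per_run=10, M=12, voxels_per_region=10,
        frac_discriminative=0.3, effect_size=2.0, rest_len=6, fixation_len=8, seed=5,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    voxels, events, truth = synth.generate_study(small_config)
    return voxels, events, truth


@pytest.fixture(scope="session")
def small_parcellation(small_config):
    return synth.synthetic_parcellation(small_config)


@pytest.fixture(scope="session")
def preprocessed_run(small_study, small_parcellation):
    """One fully preprocessed run (selection -> averaging -> z=8 splines ->
    labels -> informed noise)."""
    voxels, events, _ = small_study
    key = ("sub-01", 0)
    return prep.preprocess_run(
        voxels[key], events[key], small_parcellation, n_keep=25, z=8,
        noise=prep.NoiseConfig(seed=1),
    )


def as_prepared(W):
    """Wrap a nonnegative zero-diagonal matrix as a PreparedNetwork for metric tests."""
    W = np.asarray(W, dtype=float)
    return PreparedNetwork(W=W, node_ids=np.arange(W.shape[0]), L=_length_matrix(W))
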