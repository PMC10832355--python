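import numpy as np
import pytest

from spatialgdl import (EncoderSpec, build_feature_matrix, build_graph,
                        generate, train_dgi, train_vgae)
from spatialgdl.synthetic_data import SyntheticConfig

#: desk-scale training settings shared by the deeper tests
TRAIN_KW = dict(hidden_dim=64, out_dim=32)
EPOCHS = 60


@pytest.fixture(scope="session")
def preset_ds():
    """The 5-domain layered synthetic dataset (800 spots, 200 genes, signal 3)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def preset_fm(preset_ds):
    return build_feature_matrix(preset_ds)


@pytest.fixture(scope="session")
def preset_graph(preset_ds):
    return build_graph(preset_ds.coordinates, mode="knn", k=6)


@pytest.fixture(scope="session")
def dgi_run(preset_fm, preset_graph):
    spec = EncoderSpec(family="gcn", in_dim=preset_fm.X.shape[1], **TRAIN_KW)
    return train_dgi(preset_fm, preset_graph, spec, epochs=EPOCHS, seed=1)


@pytest.fixture(scope="session")
def vgae_run(preset_fm, preset_graph):
    spec = EncoderSpec(family="gcn", in_dim=preset_fm.X.shape[1],
                       activation="relu", **TRAIN_KW)
    return train_vgae(preset_fm, preset_graph, spec, epochs=EPOCHS, seed=1)


@pytest.fixture
def tiny_ds():
    """10 spots x 6 genes with labels, deterministic."""
    rng = np.random.default_rng(7)
    from spatialgdl import SpatialDataset
    return SpatialDataset(
        expression=rng.integers(0, 20, size=(10, 6)).astype(float),
        coordinates=rng.uniform(0, 1, size=(10, 2)),
        labels=np.repeat([0, 1], 5),
        feature_names=[f"g{j}" for j in range(6)],
        spot_ids=[f"s{i}" for i in range(10)],
    )


def random_graph(rng, n, p=0.3):
    """Random symmetric binary adjacency (zero diagonal) + coordinates."""
    import scipy.sparse as sp
    upper = rng.random((n, n)) < p
    A = np.triu(upper, k=1)
    A = (A + A.T).astype(float)
    return sp.csr_matrix(A)
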