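import numpy as np
import pytest

from drugrelink.dataio import AssociationMatrix, SimilarityMatrix
from drugrelink.synthgen import SynthConfig, generate


@pytest.fixture(scope="session")
def synth_default():
    """Default synthetic benchmark instance (seed 0)."""
    return generate(SynthConfig())


@pytest.fixture(scope="session")
def synth_small():
    """A small, fast instance for pipeline-level tests."""
    cfg = SynthConfig(n_drugs=24, n_diseases=16, n_blocks=2,
                      within_block_rate=0.5, background_rate=0.05, seed=1)
    return generate(cfg)


@pytest.fixture()
def tiny_assoc():
    """Hand-written 3 diseases x 4 drugs association matrix."""
    values = np.array([
        [1, 1, 0, 0],
        [0, 1, 1, 0],
        [1, 0, 0, 0],
    ])
    return AssociationMatrix(["e1", "e2", "e3"], ["d1", "d2", "d3", "d4"], values)


def random_association(rng, n_diseases=6, n_drugs=8, p=0.35):
    values = (rng.random((n_diseases, n_drugs)) < p).astype(int)
    return AssociationMatrix(
        [f"e{i}" for i in range(n_diseases)],
        [f"d{j}" for j in range(n_drugs)],
        values,
    )


def random_similarity(rng, ids):
    n = len(ids)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(list(ids), v)
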