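import numpy as np
import pandas as pd
import pytest

from leukimm.repertoire import Clonotype, Repertoire
from leukimm.scquant import CountMatrix


@pytest.fixture
def two_clone_repertoire():
    rep = Repertoire(
        "toy",
        [Clonotype("CASSLGYEQYF", count=8), Clonotype("CASSIRSSYEQYF", count=2)],
    )
    return rep.recompute_frequencies()


@pytest.fixture
def random_repertoire_factory():
    def make(n_clones: int, seed: int) -> Repertoire:
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 500, size=n_clones)
        rep = Repertoire(
            f"rand{seed}",
            [Clonotype(f"CASS{i:04d}F", count=int(c)) for i, c in enumerate(counts)],
        )
        return rep.recompute_frequencies()

    return make


@pytest.fixture
def small_count_matrix():
    """Deterministic 6-gene x 5-cell matrix with named QC gene classes."""
    genes = ["MT-CO1", "RPS4X", "ACTB", "GAPDH", "CD8A", "NKG7"]
    X = np.array(
        [
            [5, 50, 10, 2, 1],
            [10, 20, 30, 5, 2],
            [40, 40, 40, 40, 40],
            [40, 40, 40, 40, 40],
            [5, 10, 0, 3, 9],
            [0, 40, 20, 10, 8],
        ]
    )
    meta = pd.DataFrame(
        {"sample_id": "s1", "group": "g1", "cluster": ["A", "A", "B", "B", "B"]},
        index=pd.Index([f"bc{i}" for i in range(5)], name="barcode"),
    )
    return CountMatrix(X, genes, meta)
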