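import sys
from pathlib import Path

import numpy as np
import pytest
import scipy.sparse as sp

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rareclust.io import ExpressionMatrix
from rareclust.preprocess import Embedding
from rareclust.silhouette import ClusterLabels


def random_instance(rng, n_max=100, k_max=6, d_max=10):
    """A random embedding + labeling with at least one non-singleton
    cluster; used by the oracle-equivalence tests."""
    n = int(rng.integers(10, n_max + 1))
    d = int(rng.integers(2, d_max + 1))
    k = int(rng.integers(2, min(k_max, n // 2) + 1))
    coords = rng.normal(size=(n, d))
    labels = rng.integers(0, k, size=n)
    labels[: k] = np.arange(k)  # every cluster non-empty
    labels[k] = labels[0]  # at least one non-singleton
    cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    return (
        Embedding(coords, cell_ids),
        ClusterLabels(labels.astype(str), cell_ids),
    )


@pytest.fixture(scope="session")
def tiny_counts():
    """3 cells x 4 genes, hand-enterable numbers."""
    counts = np.array(
        [[10, 0, 5, 5], [0, 2, 2, 0], [1, 1, 1, 1]], dtype=np.int64
    )
    return ExpressionMatrix(
        sp.csr_matrix(counts),
        np.array(["cellA", "cellB", "cellC"], dtype=object),
        np.array(["g1", "g2", "g3", "g4"], dtype=object),
    )


@pytest.fixture(scope="session")
def two_group_sim():
    """Small two-cluster negative-binomial simulation: exactly 10 genes
    separate the groups (5 up in each, 4x effect on well-expressed
    genes); everything else is flat noise.  Used across module tests."""
    import numpy as np

    from rareclust.simulate import SimSpec, simulate_counts

    spec = SimSpec(
        n_cells=200,
        n_genes=300,
        proportions={"g0": 0.5, "g1": 0.5},
        de_frac=0.0,
        rare_pairs=[],
        seed=7,
    )
    _, flat = simulate_counts(spec)  # same seed => same baselines
    # plant the effects on genes expressed well enough to be detectable
    expressed = np.argsort(flat.baseline)[-60:-10]
    chosen = expressed[:: len(expressed) // 10][:10]
    extra = {
        "g0": {int(i): 2.0 for i in chosen[:5]},
        "g1": {int(i): 2.0 for i in chosen[5:]},
    }
    return simulate_counts(spec, extra_lfc=extra)
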