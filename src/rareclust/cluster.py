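"""Shared-nearest-neighbor graph construction and community detection.

The clustering primitive used both for the initial conservative broad pass
and for every reclustering trial: a kNN graph in the PCA embedding
(Euclidean), re-weighted by the Jaccard overlap of the k-neighbor sets
(self included, the convention of the Seurat ecosystem), pruned at a small
threshold, then modularity optimization (Leiden by default, classic
Louvain via igraph's multilevel algorithm as an alternative) at a
resolution ``r``.

Small ``r`` with moderate ``k`` is the "conservative" regime: large,
homogeneous communities that deliberately under-split — rare populations
are expected to be merged into neighbors at this stage and recovered later
by reclustering.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError
from .preprocess import Embedding
from .silhouette import ClusterLabels

logger = logging.getLogger(__name__)

__all__ = ["SNNGraph", "build_snn_graph", "community_detect"]

DEFAULT_PRUNE = 1.0 / 15.0


@dataclass
class SNNGraph:
    """Undirected graph with Jaccard edge weights in (0, 1]."""

    graph: ig.Graph
    k: int
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.graph.vcount()

    @property
    def n_edges(self) -> int:
        return self.graph.ecount()


def build_snn_graph(
    emb: Embedding, k: int = 20, prune: float = DEFAULT_PRUNE
) -> SNNGraph:
    """Build the shared-nearest-neighbor graph of an embedding.

    The neighbor set of each cell is its ``k`` nearest cells by Euclidean
    distance in the embedding, *including itself*.  Edge weight between two
    cells is the Jaccard index of their neighbor sets; edges with weight
    ``<= prune`` are removed.
    """
    n = emb.n_cells
    if not 2 <= k < n:
        raise ParameterError(f"k={k} must satisfy 2 <= k < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(emb.coords)
    _, idx = nn.kneighbors(emb.coords)  # self is always among the k
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    adj.data[:] = 1.0  # guard duplicate (row, col) pairs
    shared = adj @ adj.T  # |N_i ∩ N_j|
    shared = sp.triu(shared, k=1).tocoo()
    inter = shared.data
    union = 2 * k - inter
    weights = inter / union
    keep = weights > prune
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights[keep].tolist()
    return SNNGraph(g, k, emb.cell_ids)


def _canonical_labels(membership: np.ndarray) -> np.ndarray:
    """Relabel communities 0..K-1 by decreasing size; ties by first member."""
    uniq, first = np.unique(membership, return_index=True)
    sizes = np.bincount(membership)[uniq]
    order = sorted(range(len(uniq)), key=lambda i: (-sizes[i], first[i]))
    mapping = {int(uniq[i]): rank for rank, i in enumerate(order)}
    return np.array([mapping[int(m)] for m in membership])


def community_detect(
    graph: SNNGraph,
    r: float = 0.3,
    seed: int = 0,
    algorithm: str = "leiden",
) -> ClusterLabels:
    """Modularity community detection at resolution ``r``.

    Labels are returned as strings ``"0".."K-1"`` ordered by decreasing
    community size (ties broken by the smallest member index), so the
    numbering is stable across runs with the same seed.
    """
    if r <= 0:
        raise ParameterError("resolution r must be positive")
    g = graph.graph
    if g.ecount() == 0:
        logger.warning("SNN graph has no edges; returning singleton clusters")
        membership = np.arange(g.vcount())
        return ClusterLabels(
            membership.astype(str), graph.cell_ids
        )
    if algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=r,
            seed=int(seed),
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
    elif algorithm == "louvain":
        state = random.getstate()
        random.seed(int(seed))
        try:
            part = g.community_multilevel(weights="weight", resolution=r)
        finally:
            random.setstate(state)
        membership = np.asarray(part.membership)
    else:
        raise ParameterError(f"unknown algorithm {algorithm!r}")
    labels = _canonical_labels(membership).astype(str)
    return ClusterLabels(labels, graph.cell_ids)
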