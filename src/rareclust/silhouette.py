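"""Per-cell silhouette scores under cosine distance.

This is the decision statistic of the whole framework.  For a cell *i* in
cluster :math:`C_m`:

.. math::

    a(i) = \\frac{1}{|C_m| - 1} \\sum_{j \\in C_m, j \\ne i} d(i, j), \\qquad
    b(i) = \\min_{l \\ne m} \\frac{1}{|C_l|} \\sum_{j \\in C_l} d(i, j),

with :math:`d` the cosine distance :math:`1 - \\cos(x_i, x_j)`, and

.. math::

    s(i) = \\frac{b(i) - a(i)}{\\max(a(i), b(i))} \\in [-1, 1].

A cluster's *silhouette coefficient* is the mean of :math:`s(i)` over its
cells; the per-cluster *median* of :math:`s(i)` is what drags a
heterogeneous cluster below the reclustering-candidate threshold.  Low
values mean cells sit nearly as close to another cluster as to their own —
the signature of an unsplit mixture.

Cells in singleton clusters have no within-cluster distance; they are
assigned the conventional sentinel :math:`s = 0` (with :math:`a = 0`).

For large datasets the exact computation is quadratic in the number of
cells; ``silhouette_samples`` therefore supports a seeded per-cluster
subsample above a configurable cap (exact below the cap, and exact mode is
always available by raising the cap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, ValidationError
from .preprocess import Embedding

__all__ = [
    "ClusterLabels",
    "SilhouetteReport",
    "cosine_distance",
    "pairwise_distances",
    "silhouette_samples",
    "cluster_coefficients",
]


@dataclass
class ClusterLabels:
    """Per-cell categorical cluster assignment, aligned to a matrix."""

    labels: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError("labels and cell_ids differ in length")
        if len(self.labels) == 0:
            raise ValidationError("empty labeling")

    @property
    def clusters(self) -> list:
        """Distinct labels, ordered by decreasing size (ties: first seen)."""
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        first = {
            lab: i for i, lab in reversed(list(enumerate(self.labels.astype(str))))
        }
        order = sorted(
            range(len(labels)), key=lambda i: (-counts[i], first[labels[i]])
        )
        return [labels[i] for i in order]

    @property
    def sizes(self) -> dict:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels, counts.tolist()))

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "label": self.labels.astype(str)}
        )


@dataclass
class SilhouetteReport:
    """Per-cell a, b and silhouette, aligned to the scored cells."""

    cell_ids: np.ndarray
    labels: np.ndarray
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "cluster": self.labels.astype(str),
                "a": self.a,
                "b": self.b,
                "s": self.s,
            }
        )


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine distance ``1 - a.b / (|a| |b|)`` between two non-zero vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DomainError("cosine distance is undefined for a zero vector")
    return float(1.0 - np.dot(a, b) / (na * nb))


def _unit_rows(emb: Embedding) -> np.ndarray:
    x = np.asarray(emb.coords, dtype=np.float64)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = emb.cell_ids[np.flatnonzero(norms == 0)[0]]
        raise DomainError(
            f"cell {bad!r} has a zero embedding vector; "
            "cosine distance is undefined"
        )
    return x / norms[:, None]


def pairwise_distances(emb: Embedding, block_size: int = 2048) -> np.ndarray:
    """Full cosine-distance matrix, computed blockwise.

    Peak additional memory is one ``block_size x n`` slab; the returned
    matrix is exactly symmetric with a zero diagonal.
    """
    if block_size < 1:
        raise ParameterError("block_size must be positive")
    u = _unit_rows(emb)
    n = u.shape[0]
    out = np.empty((n, n), dtype=np.float64)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        out[start:stop] = 1.0 - u[start:stop] @ u.T
    np.clip(out, 0.0, 2.0, out=out)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def _check_alignment(emb: Embedding, labels: ClusterLabels) -> None:
    if len(labels) != emb.n_cells:
        raise ValidationError("labels not aligned with embedding")
    if not np.array_equal(
        labels.cell_ids.astype(str), emb.cell_ids.astype(str)
    ):
        raise ValidationError("label cell ids differ from embedding cell ids")


def silhouette_samples(
    emb: Embedding,
    labels: ClusterLabels,
    subsample_cap: int = 10_000,
    min_per_cluster: int = 50,
    seed: int = 0,
    block_size: int = 2048,
) -> SilhouetteReport:
    """Per-cell silhouette under cosine distance.

    Above ``subsample_cap`` cells the score is estimated on a seeded
    uniform subsample of at most ``cap * size_c / n`` (but at least
    ``min_per_cluster``) cells per cluster; cells outside the subsample get
    ``a = b = s = NaN`` in the report.  At or below the cap the computation
    is exact.
    """
    _check_alignment(emb, labels)
    lab = labels.labels.astype(str)
    uniq, inv = np.unique(lab, return_inverse=True)
    if len(uniq) < 2:
        raise DomainError(
            "silhouette needs at least two clusters (b is undefined)"
        )
    counts = np.bincount(inv)
    if np.all(counts <= 1):
        raise DomainError("all clusters are singletons")
    n = len(lab)
    if n > subsample_cap:
        rng = np.random.default_rng(seed)
        keep = np.zeros(n, dtype=bool)
        for c in range(len(uniq)):
            members = np.flatnonzero(inv == c)
            target = max(
                min(min_per_cluster, len(members)),
                int(round(subsample_cap * len(members) / n)),
            )
            if target >= len(members):
                keep[members] = True
            else:
                keep[rng.choice(members, size=target, replace=False)] = True
        idx = np.flatnonzero(keep)
        sub = silhouette_samples(
            Embedding(emb.coords[idx], emb.cell_ids[idx]),
            ClusterLabels(lab[idx], labels.cell_ids[idx]),
            subsample_cap=len(idx) + 1,
            block_size=block_size,
        )
        a = np.full(n, np.nan)
        b = np.full(n, np.nan)
        s = np.full(n, np.nan)
        a[idx], b[idx], s[idx] = sub.a, sub.b, sub.s
        return SilhouetteReport(labels.cell_ids, labels.labels, a, b, s)

    u = _unit_rows(emb)
    k = len(uniq)
    # per-cluster distance sums via one matmul: (1 - u u^T) summed by group
    group = np.zeros((n, k))
    group[np.arange(n), inv] = 1.0
    centroid_sum = group.T @ u  # k x d, sum of unit rows per cluster
    # sum_{j in C} d(i,j) = |C| - u_i . sum_{j in C} u_j
    dist_sums = counts[None, :] - u @ centroid_sum.T  # n x k
    np.maximum(dist_sums, 0.0, out=dist_sums)

    own = inv
    own_counts = counts[own]
    a = np.zeros(n)
    non_single = own_counts > 1
    own_sums = dist_sums[np.arange(n), own]
    a[non_single] = own_sums[non_single] / (own_counts[non_single] - 1)

    means = dist_sums / counts[None, :]
    means[np.arange(n), own] = np.inf
    b = means.min(axis=1)

    s = np.zeros(n)
    denom = np.maximum(a, b)
    ok = non_single & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    a[~non_single] = 0.0
    np.clip(s, -1.0, 1.0, out=s)
    return SilhouetteReport(labels.cell_ids, labels.labels, a, b, s)


def cluster_coefficients(
    report: SilhouetteReport, labels: ClusterLabels | None = None
) -> pd.DataFrame:
    """Per-cluster silhouette coefficient (mean of s) and median of s.

    Returns a frame with columns ``cluster, n, coef, median`` sorted by
    ascending median (most heterogeneous first).  NaN rows from a
    subsampled report are excluded from the statistics but counted in
    ``n``.
    """
    if labels is not None:
        if not np.array_equal(
            report.cell_ids.astype(str), labels.cell_ids.astype(str)
        ):
            raise ValidationError("report not aligned with labels")
    frame = report.to_frame()
    grouped = frame.groupby("cluster", sort=False)
    out = grouped.agg(
        n=("s", "size"), coef=("s", "mean"), median=("s", "median")
    ).reset_index()
    return out.sort_values(
        ["median", "cluster"], kind="stable"
    ).reset_index(drop=True)
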