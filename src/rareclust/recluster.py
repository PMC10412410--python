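"""The iterative reclustering core: flag heterogeneous broad clusters,
re-derive features within them, sweep a clustering parameter grid scored by
silhouette, and integrate winning sub-labels back.

The key mechanism is *local re-featurization*: highly variable genes and
the PCA subspace are recomputed on the candidate cluster's cells alone, so
genes that separate closely related subpopulations — but are invisible at
the scale of the whole dataset — drive the second clustering pass.  Each
``(k, r)`` grid point is scored by the mean per-cell silhouette (cosine
distance) of the resulting sub-partition on the subset embedding, and the
argmax wins; grid points whose partition is trivial (one community) or
contains a subcluster below the minimum size are discarded.

A split is only *applied* by the pipeline when the winning score clears
``accept_min_coef``: a genuinely structured cluster splits into
well-separated parts that score high locally, while forcing a split on a
homogeneous blob yields a low local silhouette — this is the package's
overclustering guard.  Cells outside the reclustered candidates keep their
labels bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import build_snn_graph, community_detect
from .config import RunConfig
from .errors import DomainError, ParameterError, ValidationError
from .io import ExpressionMatrix
from .preprocess import Embedding, compute_embedding, normalize, select_hvgs
from .silhouette import (
    ClusterLabels,
    SilhouetteReport,
    cluster_coefficients,
    silhouette_samples,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReclusterParams",
    "ReclusterResult",
    "PipelineResult",
    "flag_candidates",
    "recluster_one",
    "integrate_labels",
    "run_pipeline",
]


@dataclass(frozen=True)
class ReclusterParams:
    """One grid point of the reclustering sweep."""

    k: int
    r: float
    n_pcs: int = 30
    n_hvgs: int = 2000

    def __post_init__(self) -> None:
        if min(self.k, self.n_pcs, self.n_hvgs) <= 0 or self.r <= 0:
            raise ParameterError("all reclustering parameters must be positive")


@dataclass
class ReclusterResult:
    """Outcome of the grid sweep on one candidate (or candidate union)."""

    candidate: tuple
    grid: pd.DataFrame  # k, r, n_pcs, n_hvgs, coef, n_subclusters, kept
    best: ReclusterParams | None
    best_coef: float
    sub_labels: ClusterLabels | None
    parent_coef: float = float("nan")

    @property
    def name(self) -> str:
        return "+".join(str(c) for c in self.candidate)


@dataclass
class PipelineResult:
    """End-to-end pipeline output."""

    final_labels: ClusterLabels
    broad_labels: ClusterLabels
    embedding: Embedding
    silhouette_reports: list = field(default_factory=list)
    summaries: list = field(default_factory=list)  # one frame per depth
    recluster_results: list = field(default_factory=list)
    messages: list = field(default_factory=list)


def flag_candidates(
    summary: pd.DataFrame,
    threshold: float = 0.25,
    force_include: set | None = None,
    force_exclude: set | None = None,
) -> list[str]:
    """Reclustering candidates: clusters with median silhouette below the
    threshold, minus ``force_exclude``, plus ``force_include`` — the
    semi-supervised surface.  Ordered by ascending median (most
    heterogeneous first)."""
    if summary.empty:
        raise ValidationError("empty cluster summary")
    force_include = set(force_include or ())
    force_exclude = set(force_exclude or ())
    known = set(summary["cluster"].astype(str))
    unknown = (force_include | force_exclude) - known
    if unknown:
        raise ValidationError(f"unknown cluster(s) in force lists: {unknown}")
    ordered = summary.sort_values(["median", "cluster"], kind="stable")
    out = []
    for _, row in ordered.iterrows():
        name = str(row["cluster"])
        flagged = row["median"] < threshold
        if name in force_exclude and name not in force_include:
            continue
        if flagged or name in force_include:
            out.append(name)
    return out


def _score(values: np.ndarray, how: str) -> float:
    return float(np.median(values)) if how == "median" else float(np.mean(values))


def recluster_one(
    counts: ExpressionMatrix,
    global_labels: ClusterLabels,
    candidates,
    grid: list[ReclusterParams],
    seed: int = 0,
    min_subset: int = 50,
    min_subcluster: int = 5,
    scale_factor: float = 1e4,
    hvg_method: str = "vst_like",
    algorithm: str = "leiden",
    prune: float = 1.0 / 15.0,
    score: str = "mean",
) -> ReclusterResult:
    """Grid-sweep reclustering of one candidate cluster (or a union).

    HVGs and PCA are recomputed on the candidate's cells only.  Returns
    the full grid report and the argmax grid point (ties: highest score,
    then fewest subclusters, then smallest ``k``, then smallest ``r`` —
    the most conservative split).  If every grid point collapses to one
    community the result is "no substructure" (``best=None``).
    """
    if not grid:
        raise ParameterError("empty reclustering grid")
    candidates = tuple(
        sorted({str(c) for c in (candidates if not isinstance(candidates, str)
                                 else [candidates])})
    )
    lab = global_labels.labels.astype(str)
    mask = np.isin(lab, candidates)
    n_sub = int(mask.sum())
    if n_sub == 0:
        raise ValidationError(f"no cells carry label(s) {candidates}")
    if n_sub < min_subset:
        raise DomainError(
            f"candidate {candidates} has {n_sub} cells < min_subset={min_subset}"
        )
    subset = counts.subset_cells(mask)
    norm = normalize(subset, scale_factor)

    emb_cache: dict[tuple[int, int], Embedding] = {}
    graph_cache: dict[tuple[int, int, int], object] = {}

    def embedding_for(p: ReclusterParams) -> Embedding:
        n_hvgs = min(p.n_hvgs, norm.n_genes)
        n_pcs = min(p.n_pcs, norm.n_cells - 1, n_hvgs - 1)
        key = (n_hvgs, n_pcs)
        if key not in emb_cache:
            hvgs = select_hvgs(norm, n_hvgs, hvg_method)
            emb_cache[key] = compute_embedding(norm, hvgs, n_pcs, seed=seed)
        return emb_cache[key]

    rows = []
    evaluated: list[tuple[ReclusterParams, float, int, ClusterLabels]] = []
    for p in grid:
        if p.k >= n_sub:
            logger.info("skipping k=%d >= subset size %d", p.k, n_sub)
            continue
        emb = embedding_for(p)
        gkey = (id(emb), p.k, 0)
        if gkey not in graph_cache:
            graph_cache[gkey] = build_snn_graph(emb, p.k, prune)
        sub = community_detect(graph_cache[gkey], p.r, seed=seed,
                               algorithm=algorithm)
        sizes = list(sub.sizes.values())
        n_clusters = len(sizes)
        row = {"k": p.k, "r": p.r, "n_pcs": emb.d,
               "n_hvgs": min(p.n_hvgs, norm.n_genes),
               "n_subclusters": n_clusters, "coef": float("nan"),
               "kept": False}
        if n_clusters < 2:
            rows.append(row)
            continue
        if min(sizes) < min_subcluster:
            rows.append(row)
            continue
        rep = silhouette_samples(emb, sub, subsample_cap=max(n_sub, 100))
        coef = _score(rep.s, score)
        row.update(coef=coef, kept=True)
        rows.append(row)
        evaluated.append((p, coef, n_clusters, sub))

    grid_frame = pd.DataFrame(
        rows, columns=["k", "r", "n_pcs", "n_hvgs", "n_subclusters",
                       "coef", "kept"]
    )
    if not evaluated:
        logger.info("candidate %s: no substructure under any grid point",
                    candidates)
        return ReclusterResult(candidates, grid_frame, None, float("nan"),
                               None)
    best_p, best_coef, _, best_sub = min(
        evaluated, key=lambda t: (-t[1], t[2], t[0].k, t[0].r)
    )
    return ReclusterResult(candidates, grid_frame, best_p, best_coef,
                           best_sub)


def integrate_labels(
    global_labels: ClusterLabels,
    results: list[ReclusterResult],
    naming: str = "hierarchical",
) -> ClusterLabels:
    """Replace candidate cells' labels with ``"<parent>.<sub>"``; every
    other cell's label is untouched (bit-identical)."""
    if naming != "hierarchical":
        raise ParameterError(f"unknown naming scheme {naming!r}")
    seen: set[str] = set()
    for res in results:
        overlap = seen & set(res.candidate)
        if overlap:
            raise ValidationError(f"overlapping candidates: {overlap}")
        seen |= set(res.candidate)
    # object dtype: fixed-width string arrays would truncate "<parent>.<sub>"
    new = np.array([str(x) for x in global_labels.labels], dtype=object)
    lab = global_labels.labels.astype(str)
    for res in results:
        if res.best is None or res.sub_labels is None:
            continue
        mask = np.isin(lab, res.candidate)
        if int(mask.sum()) != len(res.sub_labels):
            raise ValidationError(
                f"sub-labels for {res.candidate} do not cover the candidate"
            )
        if not np.array_equal(
            global_labels.cell_ids[mask].astype(str),
            res.sub_labels.cell_ids.astype(str),
        ):
            raise ValidationError(
                f"sub-label cell ids misaligned for {res.candidate}"
            )
        new[mask] = np.array(
            [f"{res.name}.{s}" for s in res.sub_labels.labels.astype(str)],
            dtype=object,
        )
    return ClusterLabels(new, global_labels.cell_ids)


def run_pipeline(
    counts: ExpressionMatrix, config: RunConfig | None = None, seed: int | None = None
) -> PipelineResult:
    """Full framework: conservative broad pass, silhouette flagging,
    grid reclustering of each candidate, label integration — iterated to
    ``recluster.max_depth`` so subclusters can themselves be reclustered."""
    config = config or RunConfig()
    seed = config.seed if seed is None else int(seed)
    pp, cl, rc = config.preprocess, config.cluster, config.recluster

    norm = normalize(counts, pp.scale_factor)
    hvgs = select_hvgs(norm, min(pp.n_hvgs, norm.n_genes), pp.hvg_method)
    emb = compute_embedding(
        norm, hvgs, min(pp.n_pcs, norm.n_cells - 1, len(hvgs) - 1), seed=seed
    )
    graph = build_snn_graph(emb, cl.k, cl.prune)
    broad = community_detect(graph, cl.r, seed=seed, algorithm=cl.algorithm)
    result = PipelineResult(final_labels=broad, broad_labels=broad,
                            embedding=emb)
    if len(set(broad.labels.astype(str))) < 2:
        result.messages.append(
            "broad pass produced a single cluster; nothing to do"
        )
        return result

    sil_space = emb
    if pp.distance_space == "hvg_lognorm":
        col = {g: i for i, g in enumerate(norm.gene_ids)}
        idx = np.array([col[g] for g in hvgs.gene_ids])
        dense = np.asarray(norm.matrix[:, idx].todense())
        sil_space = Embedding(dense, norm.cell_ids)

    labels = broad
    grid = [
        ReclusterParams(
            k=k, r=r,
            n_pcs=rc.n_pcs if rc.n_pcs is not None else pp.n_pcs,
            n_hvgs=rc.n_hvgs if rc.n_hvgs is not None else pp.n_hvgs,
        )
        for k in rc.grid_k for r in rc.grid_r
    ]
    settled: set[str] = set()  # candidates already examined and kept intact
    for depth in range(rc.max_depth):
        report = silhouette_samples(
            sil_space, labels,
            subsample_cap=config.silhouette.subsample_cap,
            min_per_cluster=config.silhouette.min_per_cluster, seed=seed,
        )
        summary = cluster_coefficients(report, labels)
        result.silhouette_reports.append(report)
        result.summaries.append(summary)
        candidates = flag_candidates(
            summary, rc.threshold,
            force_include=set(rc.force_include) if depth == 0 else None,
            force_exclude=set(rc.force_exclude) if depth == 0 else None,
        )
        sizes = labels.sizes
        candidates = [
            c for c in candidates
            if sizes[c] >= rc.min_subset and c not in settled
        ]
        if not candidates:
            result.messages.append(
                f"depth {depth}: no reclustering candidates; stopping"
            )
            break
        applied = []
        for cand in candidates:
            res = recluster_one(
                counts, labels, cand, grid, seed=seed,
                min_subset=rc.min_subset, min_subcluster=rc.min_subcluster,
                scale_factor=pp.scale_factor, hvg_method=pp.hvg_method,
                algorithm=cl.algorithm, prune=cl.prune, score=rc.score,
            )
            res.parent_coef = float(
                summary.loc[summary["cluster"] == cand, "coef"].iloc[0]
            )
            result.recluster_results.append(res)
            if res.best is None:
                result.messages.append(
                    f"depth {depth}: {cand}: no substructure"
                )
                settled.add(cand)
            elif res.best_coef < rc.accept_min_coef:
                result.messages.append(
                    f"depth {depth}: {cand}: best split scores "
                    f"{res.best_coef:.3f} < accept_min_coef; kept intact"
                )
                settled.add(cand)
            else:
                applied.append(res)
        if not applied:
            result.messages.append(
                f"depth {depth}: no split accepted; stopping"
            )
            break
        labels = integrate_labels(labels, applied)
    result.final_labels = labels
    return result
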