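"""Two-step marker-gene identification with a specificity filter.

Step 1 (``candidate_markers``) contrasts the target cluster against a
*chosen background* — typically its closely related clusters rather than
everything else — with a per-gene two-sided Wilcoxon rank-sum test on
log-normalized expression, Benjamini–Hochberg correction, and a minimum
log2 fold-change.

Step 2 (``filter_markers``) removes candidates that are *highly expressed
elsewhere*: any gene in the top-expressed set (top 10% by mean normalized
expression, by default) of a cluster outside the target and the exempt set
is dropped.  This kills genes that look dramatically enriched versus the
chosen background but are in fact ubiquitous or characteristic of an
unrelated cluster — the classic failure mode of one-vs-background testing
for rare subpopulations.

By default the exempt set equals the background clusters of step 1 (they
were already contrasted directly); ``strict=True`` exempts nothing but the
target.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ParameterError
from .preprocess import NormalizedMatrix
from .silhouette import ClusterLabels

__all__ = ["candidate_markers", "top_expressed_sets", "filter_markers"]


def _check_aligned(norm: NormalizedMatrix, labels: ClusterLabels) -> None:
    if len(labels) != norm.n_cells or not np.array_equal(
        labels.cell_ids.astype(str), norm.cell_ids.astype(str)
    ):
        raise DomainError("labels are not aligned with the matrix")


def candidate_markers(
    norm: NormalizedMatrix,
    labels: ClusterLabels,
    target: str,
    background,
    alpha: float = 0.05,
    min_lfc: float = 0.25,
) -> pd.DataFrame:
    """Step-1 candidate markers of ``target`` versus ``background``.

    Returns genes with BH-adjusted two-sided Wilcoxon rank-sum
    ``p_adj < alpha`` and ``log2_fc > min_lfc`` (fold-change of expm1-scale
    means with pseudocount 1), sorted by descending ``log2_fc``.  Columns:
    ``gene_id, log2_fc, p, p_adj, pct_target, pct_background,
    passed_filter`` (the flag starts ``True``; the specificity filter may
    clear it).
    """
    _check_aligned(norm, labels)
    background = {str(b) for b in (
        background if not isinstance(background, str) else [background]
    )}
    target = str(target)
    if target in background:
        raise DomainError("target must not be part of the background")
    lab = labels.labels.astype(str)
    t_mask = lab == target
    b_mask = np.isin(lab, sorted(background))
    if not t_mask.any():
        raise DomainError(f"target cluster {target!r} is empty")
    if not b_mask.any():
        raise DomainError(f"background {sorted(background)} is empty")

    x = np.asarray(norm.matrix[t_mask].todense())
    y = np.asarray(norm.matrix[b_mask].todense())
    res = mannwhitneyu(x, y, axis=0, alternative="two-sided",
                       method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    p_adj = multipletests(p, method="fdr_bh")[1]
    mean_t = np.expm1(x).mean(axis=0)
    mean_b = np.expm1(y).mean(axis=0)
    log2_fc = np.log2(mean_t + 1.0) - np.log2(mean_b + 1.0)
    table = pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "log2_fc": log2_fc,
            "p": p,
            "p_adj": p_adj,
            "pct_target": (x > 0).mean(axis=0),
            "pct_background": (y > 0).mean(axis=0),
        }
    )
    table = table[(table["p_adj"] < alpha) & (table["log2_fc"] > min_lfc)]
    table = table.sort_values(
        ["log2_fc", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["passed_filter"] = True
    return table


def top_expressed_sets(
    norm: NormalizedMatrix, labels: ClusterLabels, pct: float = 0.10
) -> dict:
    """Per-cluster "highly expressed" gene sets: for each cluster, the
    ``ceil(pct * n_genes)`` genes with the highest mean normalized
    expression over its cells (ties broken by gene id, deterministically).
    """
    if not 0 < pct < 1:
        raise ParameterError("pct must be in (0, 1)")
    _check_aligned(norm, labels)
    n_top = ceil(pct * norm.n_genes)
    lab = labels.labels.astype(str)
    out: dict[str, set] = {}
    for cluster in sorted(set(lab)):
        means = np.asarray(norm.matrix[lab == cluster].mean(axis=0)).ravel()
        order = np.lexsort((norm.gene_ids.astype(str), -means))[:n_top]
        out[cluster] = set(norm.gene_ids[order])
    return out


def filter_markers(
    candidates: pd.DataFrame,
    top_sets: dict,
    target: str,
    exempt=None,
    strict: bool = False,
) -> pd.DataFrame:
    """Step-2 specificity filter.

    A candidate keeps ``passed_filter=True`` only if it is absent from the
    top-expressed set of every cluster outside ``{target} | exempt``.
    ``strict=True`` ignores ``exempt`` (only the target itself is spared).
    The output is the same table with the flag updated — a pure
    filtration; no gene is ever added.
    """
    target = str(target)
    exempt = set() if strict or exempt is None else {str(e) for e in exempt}
    foreign = [c for c in top_sets if c not in ({target} | exempt)]
    missing = {target} - set(top_sets)
    if missing:
        raise DomainError(f"top_sets does not cover cluster(s) {missing}")
    foreign_union: set = set()
    for c in foreign:
        foreign_union |= set(top_sets[c])
    out = candidates.copy()
    out["passed_filter"] = ~out["gene_id"].isin(foreign_union)
    return out
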