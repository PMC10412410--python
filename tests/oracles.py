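"""Independent brute-force oracles, written against the definitions only.

These deliberately share no code with the package: double loops over
cells, explicit set arithmetic, and the textbook contingency-table
formulas.  They exist so the vectorized implementations can be checked
against a transliteration of the math.
"""

from __future__ import annotations

import math

import numpy as np


def cosine_distance_naive(a, b) -> float:
    num = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return 1.0 - num / (na * nb)


def silhouette_naive(coords: np.ndarray, labels) -> dict:
    """Per-cell a, b, s by explicit double loops over cells and clusters."""
    labels = [str(x) for x in labels]
    n = len(labels)
    clusters = sorted(set(labels))
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        own_members = [j for j in range(n) if labels[j] == own and j != i]
        if own_members:
            a[i] = sum(
                cosine_distance_naive(coords[i], coords[j])
                for j in own_members
            ) / len(own_members)
        other_means = []
        for c in clusters:
            if c == own:
                continue
            members = [j for j in range(n) if labels[j] == c]
            other_means.append(
                sum(
                    cosine_distance_naive(coords[i], coords[j])
                    for j in members
                ) / len(members)
            )
        b[i] = min(other_means)
        if own_members and max(a[i], b[i]) > 0:
            s[i] = (b[i] - a[i]) / max(a[i], b[i])
    return {"a": a, "b": b, "s": s}


def snn_weights_naive(coords: np.ndarray, k: int) -> dict:
    """Jaccard weight of every cell pair from explicit k-neighbor sets
    (self included, Euclidean distance, ties by index)."""
    n = len(coords)
    neighbor_sets = []
    for i in range(n):
        dists = [(float(np.linalg.norm(coords[i] - coords[j])), j)
                 for j in range(n)]
        dists.sort()
        neighbor_sets.append({j for _, j in dists[:k]})
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            if inter:
                weights[(i, j)] = inter / union
    return weights


def ari_naive(truth, pred) -> float:
    """Adjusted Rand index from pair counting over all cell pairs."""
    truth = [str(x) for x in truth]
    pred = [str(x) for x in pred]
    n = len(truth)
    same_both = same_t = same_p = 0
    for i in range(n):
        for j in range(i + 1, n):
            t = truth[i] == truth[j]
            p = pred[i] == pred[j]
            same_t += t
            same_p += p
            same_both += t and p
    total = n * (n - 1) / 2
    expected = same_t * same_p / total
    max_index = (same_t + same_p) / 2
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)


def nmi_naive(truth, pred) -> float:
    """sqrt-normalized mutual information from explicit joint counts."""
    truth = [str(x) for x in truth]
    pred = [str(x) for x in pred]
    n = len(truth)
    joint: dict = {}
    pt: dict = {}
    pp: dict = {}
    for t, p in zip(truth, pred):
        joint[(t, p)] = joint.get((t, p), 0) + 1
        pt[t] = pt.get(t, 0) + 1
        pp[p] = pp.get(p, 0) + 1
    mi = 0.0
    for (t, p), c in joint.items():
        mi += (c / n) * math.log(c * n / (pt[t] * pp[p]))
    ht = -sum((c / n) * math.log(c / n) for c in pt.values())
    hp = -sum((c / n) * math.log(c / n) for c in pp.values())
    if ht == 0 or hp == 0:
        return 0.0
    return mi / math.sqrt(ht * hp)
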