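"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately slow and cache-free: dict-based counting
for information quantities, explicit step-by-step TOPSIS, pair counting
for AUC, and a greedy selector that re-evaluates its criterion from
scratch at every step.  Nothing below imports the production code paths
it is used to check, except the public estimator API where the contract
under test is the greedy *search*, not the estimator.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

from frmt.infotheory import (
    DiscreteVector,
    conditional_mutual_information,
    joint_entropy,
    joint_mutual_information,
    merge,
    mutual_information,
)


# ---------------------------------------------------------------------------
# counting-based information quantities (independent of numpy/bincount path)
# ---------------------------------------------------------------------------

def entropy_counts(samples) -> float:
    """H from a plain Counter over hashable symbols."""
    c = Counter(samples)
    n = sum(c.values())
    return -sum((k / n) * math.log2(k / n) for k in c.values())


def mi_counts(x, y) -> float:
    """I(X;Y) by direct summation over the empirical joint."""
    n = len(x)
    cx, cy = Counter(x), Counter(y)
    cxy = Counter(zip(x, y))
    total = 0.0
    for (a, b), k in cxy.items():
        pxy = k / n
        total += pxy * math.log2(pxy / ((cx[a] / n) * (cy[b] / n)))
    return total


def cmi_counts(x, y, z) -> float:
    """I(X;Y|Z) as sum_z p(z) I(X;Y|Z=z), each slice via mi_counts."""
    x, y, z = list(x), list(y), list(z)
    n = len(x)
    total = 0.0
    for zv, nz in Counter(z).items():
        idx = [i for i in range(n) if z[i] == zv]
        total += (nz / n) * mi_counts([x[i] for i in idx], [y[i] for i in idx])
    return total


# ---------------------------------------------------------------------------
# TOPSIS, step by step
# ---------------------------------------------------------------------------

def brute_topsis(x, weights, benefit_mask=None):
    """Explicit loop implementation of the seven-step procedure.

    Returns (H, order).  All-benefit by default.
    """
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if benefit_mask is None:
        benefit_mask = [True] * n

    u = np.zeros_like(x)
    for j in range(n):
        norm = math.sqrt(sum(x[i, j] ** 2 for i in range(m)))
        for i in range(m):
            u[i, j] = x[i, j] / norm if norm > 0 else 0.0
    v = np.zeros_like(x)
    for j in range(n):
        for i in range(m):
            v[i, j] = w[j] * u[i, j]
    a_plus = [
        max(v[:, j]) if benefit_mask[j] else min(v[:, j]) for j in range(n)
    ]
    a_minus = [
        min(v[:, j]) if benefit_mask[j] else max(v[:, j]) for j in range(n)
    ]
    h = np.zeros(m)
    for i in range(m):
        p_plus = math.sqrt(sum((v[i, j] - a_plus[j]) ** 2 for j in range(n)))
        p_minus = math.sqrt(sum((v[i, j] - a_minus[j]) ** 2 for j in range(n)))
        h[i] = 0.5 if p_plus + p_minus == 0 else p_minus / (p_plus + p_minus)
    order = sorted(range(m), key=lambda i: (-h[i], i))
    return h, np.array(order)


# ---------------------------------------------------------------------------
# AUC by pair counting
# ---------------------------------------------------------------------------

def brute_auc(scores, labels, positive=1) -> float:
    """Fraction of positive-negative pairs correctly ordered, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            wins += 1.0
        elif p == q:
            wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# MCC straight from the formula
# ---------------------------------------------------------------------------

def brute_mcc(tp, fp, tn, fn) -> float:
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else num / den


# ---------------------------------------------------------------------------
# no-cache greedy selection
# ---------------------------------------------------------------------------

def _step_score(criterion, k, selected, feats, y, beta):
    rel = mutual_information(feats[k], y)
    if not selected:
        return rel
    if criterion == "mim":
        return rel
    if criterion == "mifs":
        return rel - beta * sum(mutual_information(feats[k], feats[j]) for j in selected)
    if criterion == "mrmr":
        return rel - sum(
            mutual_information(feats[k], feats[j]) for j in selected
        ) / len(selected)
    if criterion == "jmi":
        return sum(
            joint_mutual_information(feats[k], feats[j], y)
            - mutual_information(feats[j], y)
            for j in selected
        ) / len(selected)
    if criterion == "disr":
        total = 0.0
        for j in selected:
            h = joint_entropy(feats[k], feats[j], y)
            if h > 0.0:
                total += joint_mutual_information(feats[k], feats[j], y) / h
        return total / len(selected)
    if criterion == "cmim":
        return min(
            conditional_mutual_information(feats[k], y, feats[j]) for j in selected
        )
    if criterion == "icap":
        return rel - sum(
            max(
                0.0,
                mutual_information(feats[k], feats[j])
                - conditional_mutual_information(feats[k], feats[j], y),
            )
            for j in selected
        )
    if criterion == "cife":
        return rel - sum(
            mutual_information(feats[k], feats[j])
            - conditional_mutual_information(feats[k], feats[j], y)
            for j in selected
        )
    raise ValueError(criterion)


def brute_greedy(criterion, feats, y, beta=1.0):
    """Forward selection re-evaluating the step score from scratch at
    every step (no caching, no shared state).  Returns (order, scores)."""
    m = len(feats)
    remaining = list(range(m))
    selected: list[int] = []
    scores: list[float] = []
    while remaining:
        best_k, best_j = None, None
        for k in remaining:  # ascending index -> spec tie-break
            j = _step_score(criterion, k, selected, feats, y, beta)
            if best_j is None or j > best_j:
                best_k, best_j = k, j
        selected.append(best_k)
        scores.append(best_j)
        remaining.remove(best_k)
    return np.array(selected), np.array(scores)


def random_discrete_dataset(rng, n_features=None, n_samples=None, max_cats=4):
    """A random small discrete dataset (feature DiscreteVectors, y)."""
    n_features = n_features or rng.integers(2, 9)
    n_samples = n_samples or rng.integers(8, 31)
    feats = []
    for _ in range(n_features):
        k = int(rng.integers(2, max_cats + 1))
        feats.append(DiscreteVector.from_codes(rng.integers(0, k, size=n_samples)))
    y_codes = rng.integers(0, 2, size=n_samples)
    if min((y_codes == 0).sum(), (y_codes == 1).sum()) < 2:
        y_codes[:4] = [0, 0, 1, 1]
    y = DiscreteVector.from_codes(y_codes)
    return feats, y


__all__ = [
    "entropy_counts",
    "mi_counts",
    "cmi_counts",
    "brute_topsis",
    "brute_auc",
    "brute_mcc",
    "brute_greedy",
    "random_discrete_dataset",
    "merge",
]
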