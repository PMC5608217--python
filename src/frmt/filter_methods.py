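"""The ten filter feature-selection criteria, each ranking all features.

Two statistical tests (``ttest``, ``wrs``) score the continuous values
directly; the eight greedy information-theoretic criteria (``mim``,
``mifs``, ``mrmr``, ``jmi``, ``disr``, ``cmim``, ``icap``, ``cife``)
run forward selection to full depth on discretized features.  With S the
set already selected and X_k a candidate, the step scores are

    mim:  J = I(X_k;Y)
    mifs: J = I(X_k;Y) - beta * sum_{j in S} I(X_k;X_j)
    mrmr: J = I(X_k;Y) - (1/|S|) sum_{j in S} I(X_k;X_j)
    jmi:  J = (1/|S|) sum_{j in S} [I(X_k,X_j;Y) - I(X_j;Y)]
    disr: J = (1/|S|) sum_{j in S} I(X_k,X_j;Y) / H(X_k,X_j,Y)
    cmim: J = min_{j in S} I(X_k;Y|X_j)
    icap: J = I(X_k;Y) - sum_{j in S} max(0, I(X_k;X_j) - I(X_k;X_j|Y))
    cife: J = I(X_k;Y) - sum_{j in S} (I(X_k;X_j) - I(X_k;X_j|Y))

with the first pick of every criterion being argmax I(X_k;Y), and ties
broken everywhere by ascending feature index.

The jmi/disr scores above differ from the textbook running sums
(sum_{j in S} I(X_k,X_j;Y), resp. its symmetric-relevance form) only by
a per-step affine map that is constant across candidates — subtracting
sum_j I(X_j;Y) and/or dividing by |S| cannot change any argmax — so the
selection order is exactly the classical one while the recorded scores
stay on a per-partner scale that is comparable across steps (jmi's form
equals the mean conditional relevance (1/|S|) sum_j I(X_k;Y|X_j)).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._exceptions import ParameterError
from .infotheory import (
    DiscreteVector,
    conditional_mutual_information,
    discretize,
    joint_entropy,
    joint_mutual_information,
    mutual_information,
)
from .io_core import POSITIVE, ExpressionDataset, RankingResult

GREEDY_CRITERIA = ("mim", "mifs", "mrmr", "jmi", "disr", "cmim", "icap", "cife")
METHOD_ORDER = ("ttest", "wrs") + GREEDY_CRITERIA

DEFAULT_N_BINS = 10
DEFAULT_MIFS_BETA = 1.0


def _order_by_score(scores: np.ndarray) -> np.ndarray:
    """Descending score, ties by ascending feature index."""
    return np.lexsort((np.arange(scores.size), -scores))


def rank_ttest(data: ExpressionDataset) -> RankingResult:
    """Rank by |t| of the Welch two-sample t statistic.

    A zero-variance feature scores 0 when class means agree and +inf
    (ranked first) when they differ.
    """
    data.require_two_classes()
    pos = data.matrix[data.labels == POSITIVE]
    neg = data.matrix[data.labels != POSITIVE]
    m1, m2 = pos.mean(axis=0), neg.mean(axis=0)
    v1, v2 = pos.var(axis=0, ddof=1), neg.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / pos.shape[0] + v2 / neg.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / denom
    zero_var = denom == 0
    t[zero_var & (m1 == m2)] = 0.0
    t[zero_var & (m1 != m2)] = np.inf
    order = _order_by_score(t)
    return RankingResult(
        method_name="ttest",
        ordered_features=order,
        scores=t[order],
        params={"variant": "welch"},
        feature_names=list(data.feature_names),
    )


def rank_wilcoxon(data: ExpressionDataset) -> RankingResult:
    """Rank by |z| of the rank-sum normal approximation (midrank ties,
    no continuity correction)."""
    pos = data.matrix[data.labels == POSITIVE]
    neg = data.matrix[data.labels != POSITIVE]
    scores = np.empty(data.n_features)
    for j in range(data.n_features):
        scores[j] = abs(stats.ranksums(pos[:, j], neg[:, j]).statistic)
    order = _order_by_score(scores)
    return RankingResult(
        method_name="wrs",
        ordered_features=order,
        scores=scores[order],
        params={"ties": "midrank", "continuity_correction": False},
        feature_names=list(data.feature_names),
    )


class PairStatsCache:
    """Memoized pairwise information quantities for one discretized dataset.

    Shared across the eight greedy criteria so that each unordered
    feature pair is evaluated at most once per quantity.  All values are
    produced by the public estimators in :mod:`frmt.infotheory`, so the
    cached path is bit-identical to direct evaluation.
    """

    def __init__(self, features: list[DiscreteVector], y: DiscreteVector):
        self.features = features
        self.y = y
        self.relevance = np.array(
            [mutual_information(f, y) for f in features]
        )
        self._pair: dict[tuple[int, int, str], float] = {}

    def _get(self, a: int, b: int, key: str) -> float:
        tag = (a, b, key)
        if tag not in self._pair:
            fa, fb, y = self.features[a], self.features[b], self.y
            if key == "mi":
                val = mutual_information(fa, fb)
            elif key == "cmi_given_y":
                val = conditional_mutual_information(fa, fb, y)
            elif key == "jmi":
                val = joint_mutual_information(fa, fb, y)
            elif key == "h3":
                val = joint_entropy(fa, fb, y)
            elif key == "cmi_y":
                val = conditional_mutual_information(fa, y, fb)
            else:  # pragma: no cover
                raise KeyError(key)
            self._pair[tag] = val
            if key in {"mi", "cmi_given_y", "jmi", "h3"}:  # symmetric in (a, b)
                self._pair[(b, a, key)] = val
        return self._pair[tag]

    def mi(self, k: int, j: int) -> float:
        return self._get(k, j, "mi")

    def mi_given_class(self, k: int, j: int) -> float:
        """I(X_k;X_j|Y)."""
        return self._get(k, j, "cmi_given_y")

    def pair_relevance(self, k: int, j: int) -> float:
        """I(X_k,X_j;Y)."""
        return self._get(k, j, "jmi")

    def pair_joint_entropy(self, k: int, j: int) -> float:
        """H(X_k,X_j,Y)."""
        return self._get(k, j, "h3")

    def class_mi_given_feature(self, k: int, j: int) -> float:
        """I(X_k;Y|X_j) — note the asymmetry in (k, j)."""
        return self._get(k, j, "cmi_y")


def discretize_dataset(
    data: ExpressionDataset, n_bins: int = DEFAULT_N_BINS, strategy: str = "equal_frequency"
) -> tuple[list[DiscreteVector], DiscreteVector]:
    """Per-feature discretization plus the (already discrete) class vector."""
    features = [
        discretize(data.matrix[:, j], n_bins, strategy) for j in range(data.n_features)
    ]
    y = DiscreteVector((data.labels == POSITIVE).astype(np.int64), 2)
    return features, y


def _greedy_step_scores(
    criterion: str,
    cache: PairStatsCache,
    remaining: list[int],
    selected: list[int],
    beta: float,
) -> np.ndarray:
    rel = cache.relevance
    J = np.empty(len(remaining))
    for pos, k in enumerate(remaining):
        if not selected:
            J[pos] = rel[k]
            continue
        if criterion == "mim":
            J[pos] = rel[k]
        elif criterion == "mifs":
            J[pos] = rel[k] - beta * sum(cache.mi(k, j) for j in selected)
        elif criterion == "mrmr":
            J[pos] = rel[k] - sum(cache.mi(k, j) for j in selected) / len(selected)
        elif criterion == "jmi":
            J[pos] = sum(
                cache.pair_relevance(k, j) - rel[j] for j in selected
            ) / len(selected)
        elif criterion == "disr":
            total = 0.0
            for j in selected:
                h = cache.pair_joint_entropy(k, j)
                if h > 0.0:
                    total += cache.pair_relevance(k, j) / h
            J[pos] = total / len(selected)
        elif criterion == "cmim":
            J[pos] = min(cache.class_mi_given_feature(k, j) for j in selected)
        elif criterion == "icap":
            J[pos] = rel[k] - sum(
                max(0.0, cache.mi(k, j) - cache.mi_given_class(k, j))
                for j in selected
            )
        elif criterion == "cife":
            J[pos] = rel[k] - sum(
                cache.mi(k, j) - cache.mi_given_class(k, j) for j in selected
            )
        else:
            raise ParameterError(f"unknown greedy criterion {criterion!r}")
    return J


def rank_greedy(
    criterion: str,
    data: ExpressionDataset,
    n_bins: int = DEFAULT_N_BINS,
    beta: float = DEFAULT_MIFS_BETA,
    strategy: str = "equal_frequency",
    _cache: PairStatsCache | None = None,
) -> RankingResult:
    """Forward selection to full depth under one greedy criterion."""
    if criterion not in GREEDY_CRITERIA:
        raise ParameterError(
            f"unknown criterion {criterion!r}; expected one of {GREEDY_CRITERIA}"
        )
    data.require_two_classes()
    if _cache is None:
        features, y = discretize_dataset(data, n_bins, strategy)
        _cache = PairStatsCache(features, y)

    m = data.n_features
    remaining = list(range(m))
    selected: list[int] = []
    step_scores: list[float] = []
    while remaining:
        J = _greedy_step_scores(criterion, _cache, remaining, selected, beta)
        best = int(np.argmax(J))  # first max -> ascending-index tie-break
        step_scores.append(float(J[best]))
        selected.append(remaining.pop(best))

    params = {"n_bins": n_bins, "strategy": strategy}
    if criterion == "mifs":
        params["beta"] = beta
    return RankingResult(
        method_name=criterion,
        ordered_features=np.array(selected),
        scores=np.array(step_scores),
        params=params,
        feature_names=list(data.feature_names),
    )


def rank_method(
    method: str,
    data: ExpressionDataset,
    n_bins: int = DEFAULT_N_BINS,
    beta: float = DEFAULT_MIFS_BETA,
) -> RankingResult:
    """Dispatch a single criterion by name (``ttest``/``wrs``/greedy)."""
    if method == "ttest":
        return rank_ttest(data)
    if method == "wrs":
        return rank_wilcoxon(data)
    return rank_greedy(method, data, n_bins=n_bins, beta=beta)


def rank_all_methods(
    data: ExpressionDataset,
    n_bins: int = DEFAULT_N_BINS,
    beta: float = DEFAULT_MIFS_BETA,
) -> list[RankingResult]:
    """All ten rankings in the fixed order :data:`METHOD_ORDER`.

    The greedy criteria share one discretization and one pairwise-stat
    cache, which keeps the full sweep near O(m^2) pair evaluations.
    """
    data.require_two_classes()
    features, y = discretize_dataset(data, n_bins)
    cache = PairStatsCache(features, y)
    results = [rank_ttest(data), rank_wilcoxon(data)]
    for criterion in GREEDY_CRITERIA:
        results.append(
            rank_greedy(criterion, data, n_bins=n_bins, beta=beta, _cache=cache)
        )
    return results
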