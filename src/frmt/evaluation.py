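"""Repeated stratified cross-validation, MCC/AUC scoring, and the
winning-frequency / best-method analyses over an evaluation grid.

The positive class is the early stage (+1) throughout; MCC's TP counts
early-stage hits.  Classifiers are consumed through a small adapter
contract (``fit`` / ``predict`` / ``decision_scores``) so their internals
stay out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._exceptions import (
    CoverageError,
    EvaluationError,
    ParameterError,
    StratificationError,
    ValidationError,
)
from .filter_methods import METHOD_ORDER, rank_all_methods, rank_method
from .io_core import NEGATIVE, POSITIVE, ExpressionDataset, RankingResult
from .topsis_ranker import frmt_rank

SELECTOR_ORDER = ("frmt",) + METHOD_ORDER
DEFAULT_CLASSIFIERS = ("svm", "rf", "dt", "lda", "nb", "fl", "knn")
DEFAULT_SUBSET_SIZES = (5, 10, 15, 20)


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; positive class = early stage."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == POSITIVE, y_pred == POSITIVE
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, defined as
    0 when any marginal in the denominator is zero.
    """
    num = c.tp * c.tn - c.fp * c.fn
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return num / np.sqrt(den)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, midrank ties.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[pos].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# classifier adapters
# ---------------------------------------------------------------------------

class ClassifierAdapter:
    """Wraps an estimator exposing ``fit(X, y)`` and ``predict(X)``.

    ``decision_scores`` returns a continuous positive-class score; if
    the wrapped model offers none, predicted labels serve as 0/1 scores.
    """

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter":
        self.estimator.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            col = list(est.classes_).index(POSITIVE)
            return np.asarray(proba[:, col])
        if hasattr(est, "decision_function"):
            scores = np.asarray(est.decision_function(X))
            # sklearn orients decision_function toward classes_[1]
            if est.classes_[1] != POSITIVE:
                scores = -scores
            return scores
        return (self.predict(X) == POSITIVE).astype(float)


class FuzzyGaussianClassifier:
    """Minimal fuzzy-inference classifier: one rule per class with
    Gaussian membership functions per feature and a product t-norm.

    The firing strength of class c at x is prod_j exp(-(x_j - m_cj)^2 /
    (2 s_cj^2)); prediction is the class with the larger strength.
    """

    _SD_FLOOR = 1e-6

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FuzzyGaussianClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        self._params = {}
        for c in self.classes_:
            Xc = X[y == c]
            if Xc.shape[0] == 0:
                raise EvaluationError("fuzzy classifier needs both classes to fit")
            sd = Xc.std(axis=0, ddof=0)
            self._params[int(c)] = (Xc.mean(axis=0), np.maximum(sd, self._SD_FLOOR))
        return self

    def _log_strength(self, X: np.ndarray, c: int) -> np.ndarray:
        m, s = self._params[c]
        return -(((X - m) / s) ** 2 / 2.0).sum(axis=1)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._log_strength(X, POSITIVE) - self._log_strength(X, NEGATIVE)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, POSITIVE, NEGATIVE)


def make_classifier(name: str, seed: int = 0, fast: bool = False) -> ClassifierAdapter:
    """Build a roster classifier by short name.

    ``fast=True`` shrinks ensemble sizes for test/benchmark budgets
    without changing the adapter contract.
    """
    name = name.lower()
    if name == "svm":
        est = SVC(kernel="rbf", gamma="scale", random_state=seed)
    elif name == "rf":
        est = RandomForestClassifier(
            n_estimators=25 if fast else 100, random_state=seed
        )
    elif name == "dt":
        est = DecisionTreeClassifier(random_state=seed)
    elif name == "lda":
        est = LinearDiscriminantAnalysis()
    elif name == "nb":
        est = GaussianNB()
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=5)
    elif name == "fl":
        est = FuzzyGaussianClassifier()
    else:
        raise ParameterError(f"unknown classifier {name!r}")
    return ClassifierAdapter(name, est)


def make_roster(
    names: Iterable[str] = DEFAULT_CLASSIFIERS, seed: int = 0, fast: bool = False
) -> list[str]:
    """Validate a classifier roster (adapters are built per fit)."""
    names = list(names)
    for n in names:
        make_classifier(n, seed=seed, fast=fast)  # raises on unknown names
    return names


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def compute_rankings(
    data: ExpressionDataset,
    selector_names: Sequence[str],
    n_bins: int = 10,
) -> dict[str, RankingResult]:
    """Rankings for the requested selectors, sharing work where possible.

    If more than one information-theoretic selector (or ``frmt``) is
    requested, all ten base methods are computed once and reused; the
    ``frmt`` fusion then aggregates those same base rankings.
    """
    for name in selector_names:
        if name not in SELECTOR_ORDER:
            raise ParameterError(f"unknown selector {name!r}")
    heavy = [n for n in selector_names if n not in ("ttest", "wrs")]
    out: dict[str, RankingResult] = {}
    if len(heavy) > 1 or "frmt" in selector_names:
        base = {r.method_name: r for r in rank_all_methods(data, n_bins=n_bins)}
        for name in selector_names:
            if name == "frmt":
                out[name] = frmt_rank(
                    data, n_bins=n_bins, rankings=[base[m] for m in METHOD_ORDER]
                )
            else:
                out[name] = base[name]
    else:
        for name in selector_names:
            out[name] = rank_method(name, data, n_bins=n_bins)
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    counts = (int((labels == POSITIVE).sum()), int((labels == NEGATIVE).sum()))
    if min(counts) < n_folds:
        raise StratificationError(
            f"cannot make {n_folds} stratified folds with class counts {counts}: "
            "the minority class would leave some folds single-class"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    splits = list(skf.split(np.zeros(labels.size), labels))
    for train, _ in splits:
        tr = labels[train]
        if (tr == POSITIVE).sum() == 0 or (tr == NEGATIVE).sum() == 0:
            raise StratificationError("a training split contains a single class")
    return splits


def cross_validate(
    data: ExpressionDataset,
    selector_name: str,
    subset_size: int,
    classifier_name: str,
    n_folds: int = 10,
    n_repeats: int = 30,
    rank_scope: str = "per_fold",
    seed: int = 0,
    n_bins: int = 10,
    fast: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated stratified k-fold CV for one selector/classifier cell.

    Returns per-repeat arrays (MCC, AUC) computed on the pooled held-out
    predictions of each repeat.  In ``per_fold`` scope the selector is
    re-fit on each training split; in ``global`` scope it is fit once on
    the full dataset before splitting (optimistic, but mirrors ranking a
    cohort once).
    """
    if subset_size > data.n_features or subset_size < 1:
        raise ParameterError(
            f"subset_size must be in [1, {data.n_features}], got {subset_size}"
        )
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    if rank_scope not in ("per_fold", "global"):
        raise ParameterError(f"unknown rank_scope {rank_scope!r}")
    grid = run_evaluation_grid(
        datasets=[("data", data)],
        classifier_names=[classifier_name],
        selector_names=[selector_name],
        subset_sizes=[subset_size],
        n_folds=n_folds,
        n_repeats=n_repeats,
        rank_scope=rank_scope,
        seed=seed,
        n_bins=n_bins,
        fast=fast,
        keep_repeats=True,
    )
    row = grid.attrs["repeat_level"][("data", classifier_name, selector_name, subset_size)]
    return np.asarray(row["mcc"]), np.asarray(row["auc"])


def run_evaluation_grid(
    datasets: Sequence[tuple[str, ExpressionDataset]],
    classifier_names: Sequence[str] = DEFAULT_CLASSIFIERS,
    selector_names: Sequence[str] = SELECTOR_ORDER,
    subset_sizes: Sequence[int] = DEFAULT_SUBSET_SIZES,
    n_folds: int = 10,
    n_repeats: int = 30,
    rank_scope: str = "per_fold",
    seed: int = 0,
    n_bins: int = 10,
    fast: bool = False,
    keep_repeats: bool = False,
) -> pd.DataFrame:
    """Evaluate every (dataset x classifier x selector x subset size) cell.

    Returns a tidy frame with per-cell mean MCC/AUC and their standard
    errors across repeats (SE = sd of repeat-level means / sqrt(repeats)).
    Rankings are cached per training split and shared across classifiers
    and subset sizes (greedy rankings are full-depth, so a subset size is
    a prefix).
    """
    classifier_names = make_roster(classifier_names, seed=seed, fast=fast)
    subset_sizes = sorted(set(int(s) for s in subset_sizes))
    rows = []
    repeat_level: dict[tuple, dict[str, list[float]]] = {}

    for dataset_id, data in datasets:
        data.require_two_classes()
        if max(subset_sizes) > data.n_features:
            raise ParameterError(
                f"subset size {max(subset_sizes)} exceeds "
                f"{data.n_features} features in {dataset_id!r}"
            )
        global_rankings = (
            compute_rankings(data, selector_names, n_bins=n_bins)
            if rank_scope == "global"
            else None
        )
        # accumulators: key -> list of per-repeat metric values
        cell: dict[tuple, dict[str, list[float]]] = {
            (dataset_id, c, s, k): {"mcc": [], "auc": []}
            for c in classifier_names
            for s in selector_names
            for k in subset_sizes
        }
        for rep in range(n_repeats):
            rep_seed = seed * 100003 + rep
            splits = _stratified_folds(data.labels, n_folds, rep_seed)
            # pooled out-of-fold predictions per (classifier, selector, size)
            pooled: dict[tuple, dict[str, list]] = {
                (c, s, k): {"true": [], "pred": [], "score": []}
                for c in classifier_names
                for s in selector_names
                for k in subset_sizes
            }
            for train_idx, test_idx in splits:
                train = data.subset_samples(train_idx)
                if rank_scope == "per_fold":
                    rankings = compute_rankings(train, selector_names, n_bins=n_bins)
                else:
                    rankings = global_rankings
                y_train = data.labels[train_idx]
                y_test = data.labels[test_idx]
                for s in selector_names:
                    order = rankings[s].ordered_features
                    for k in subset_sizes:
                        cols = order[:k]
                        X_train = data.matrix[np.ix_(train_idx, cols)]
                        X_test = data.matrix[np.ix_(test_idx, cols)]
                        for c in classifier_names:
                            clf = make_classifier(c, seed=rep_seed, fast=fast)
                            clf.fit(X_train, y_train)
                            bucket = pooled[(c, s, k)]
                            bucket["true"].extend(y_test)
                            bucket["pred"].extend(clf.predict(X_test))
                            bucket["score"].extend(clf.decision_scores(X_test))
            for (c, s, k), bucket in pooled.items():
                y_true = np.array(bucket["true"])
                counts = ConfusionCounts.from_predictions(y_true, np.array(bucket["pred"]))
                cell[(dataset_id, c, s, k)]["mcc"].append(mcc(counts))
                cell[(dataset_id, c, s, k)]["auc"].append(
                    auc(np.array(bucket["score"]), y_true)
                )
        for key, vals in cell.items():
            d, c, s, k = key
            m_arr, a_arr = np.array(vals["mcc"]), np.array(vals["auc"])
            rows.append(
                {
                    "dataset_id": d,
                    "classifier": c,
                    "selector": s,
                    "subset_size": k,
                    "mcc_mean": m_arr.mean(),
                    "mcc_se": _se(m_arr),
                    "auc_mean": a_arr.mean(),
                    "auc_se": _se(a_arr),
                    "n_repeats": n_repeats,
                    "n_folds": n_folds,
                    "seed": seed,
                }
            )
            if keep_repeats:
                repeat_level[key] = vals
    grid = pd.DataFrame(rows)
    if keep_repeats:
        grid.attrs["repeat_level"] = repeat_level
    return grid


def _se(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


# ---------------------------------------------------------------------------
# grid analyses
# ---------------------------------------------------------------------------

def _check_coverage(grid: pd.DataFrame) -> None:
    expected = None
    missing = []
    selectors = sorted(grid["selector"].unique())
    for (d, c, k), block in grid.groupby(["dataset_id", "classifier", "subset_size"]):
        got = sorted(block["selector"].unique())
        if expected is None:
            expected = selectors
        absent = set(selectors) - set(got)
        if absent:
            missing.append((d, c, k, sorted(absent)))
    if missing:
        raise CoverageError(f"grid incomplete; missing selector cells: {missing[:5]}")


def winning_frequency(
    grid: pd.DataFrame,
    metric: str = "mcc",
    group_by: str = "overall",
    subset_size: int | None = None,
) -> pd.DataFrame:
    """Percentage of (dataset x classifier) states each selector wins.

    The winner of a state is the selector with the best mean metric;
    exact ties split the win fractionally.  Percentages sum to 100 per
    group.  ``group_by`` is one of ``subset_size`` (one group per size),
    ``dataset`` or ``overall`` (both at a single subset size, which must
    be given explicitly when the grid holds several).
    """
    if metric not in ("mcc", "auc"):
        raise ParameterError(f"metric must be 'mcc' or 'auc', got {metric!r}")
    if group_by not in ("subset_size", "dataset", "overall"):
        raise ParameterError(f"unknown group_by {group_by!r}")
    _check_coverage(grid)
    col = f"{metric}_mean"
    if group_by != "subset_size":
        sizes = sorted(grid["subset_size"].unique())
        if subset_size is None:
            if len(sizes) > 1:
                raise ParameterError(
                    f"grid holds subset sizes {sizes}; pass subset_size explicitly"
                )
            subset_size = sizes[0]
        grid = grid[grid["subset_size"] == subset_size]
        if grid.empty:
            raise CoverageError(f"no rows at subset_size={subset_size}")

    selectors = sorted(grid["selector"].unique())
    group_col = {"subset_size": "subset_size", "dataset": "dataset_id"}.get(group_by)
    records = []
    groups = grid.groupby(group_col) if group_col else [("all", grid)]
    for group_key, block in groups:
        wins = {s: 0.0 for s in selectors}
        n_states = 0
        for _, state in block.groupby(["dataset_id", "classifier"]):
            n_states += 1
            best = state[col].max()
            tied = state.loc[state[col] == best, "selector"].tolist()
            for s in tied:
                wins[s] += 1.0 / len(tied)
        for s in selectors:
            records.append(
                {
                    "group": group_key,
                    "selector": s,
                    "wins": wins[s],
                    "n_states": n_states,
                    "percent": 100.0 * wins[s] / n_states,
                }
            )
    return pd.DataFrame(records)


def _pm(mean: float, se: float) -> str:
    return f"{mean:.4f}±{se:.4f}"


def best_method_summary(
    grid: pd.DataFrame,
    subset_size: int | None = None,
    reference_selector: str = "frmt",
) -> pd.DataFrame:
    """Per-dataset best (classifier, MCC, AUC) for the reference selector
    and for the best competing selector; selection by MCC, AUC tie-break.

    The report carries both numeric columns and "mean±SE" strings.
    """
    _check_coverage(grid)
    sizes = sorted(grid["subset_size"].unique())
    if subset_size is None:
        subset_size = 10 if 10 in sizes else sizes[0]
    block = grid[grid["subset_size"] == subset_size]
    if block.empty:
        raise CoverageError(f"no rows at subset_size={subset_size}")
    rows = []
    for dataset_id, d_block in block.groupby("dataset_id"):
        ref = d_block[d_block["selector"] == reference_selector]
        others = d_block[d_block["selector"] != reference_selector]
        for label, sub in (("reference", ref), ("best_other", others)):
            if sub.empty:
                continue
            best = sub.sort_values(
                ["mcc_mean", "auc_mean"], ascending=False, kind="mergesort"
            ).iloc[0]
            rows.append(
                {
                    "dataset_id": dataset_id,
                    "role": label,
                    "selector": best["selector"],
                    "classifier": best["classifier"],
                    "mcc_mean": best["mcc_mean"],
                    "mcc_se": best["mcc_se"],
                    "auc_mean": best["auc_mean"],
                    "auc_se": best["auc_se"],
                    "mcc": _pm(best["mcc_mean"], best["mcc_se"]),
                    "auc": _pm(best["auc_mean"], best["auc_se"]),
                    "subset_size": subset_size,
                }
            )
    return pd.DataFrame(rows)
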