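"""TOPSIS aggregation and the FRMT ensemble ranking pipeline.

TOPSIS scores each alternative by its relative closeness H to the
positive ideal solution: the decision matrix is column-normalized to
unit Euclidean norm, weighted, the per-criterion ideal (best) and
anti-ideal (worst) vectors are formed, and

    H_i = P_i^- / (P_i^+ + P_i^-)

where P_i^+/P_i^- are Euclidean distances to the ideal/anti-ideal.
H_i = 1 marks the highest possible rank and H_i = 0 the lowest.

FRMT builds the decision matrix from the ten filter rankings — features
are the alternatives, criteria are the ranking methods — and returns the
descending-H order as a single fused ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ConsistencyError, ParameterError, ValidationError
from .filter_methods import (
    DEFAULT_MIFS_BETA,
    DEFAULT_N_BINS,
    rank_all_methods,
)
from .io_core import ExpressionDataset, RankingResult


@dataclass
class DecisionMatrix:
    """m alternatives x n criteria score matrix with criterion weights.

    ``benefit_mask[j]`` is True when larger scores are better under
    criterion j (the FRMT pipeline is all-benefit; the cost direction is
    kept for library users).
    """

    x: np.ndarray
    weights: np.ndarray
    benefit_mask: np.ndarray
    alternative_names: list[str] = field(default_factory=list)
    criterion_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.size == 0:
            raise ValidationError("decision matrix must be non-empty 2-d")
        m, n = self.x.shape
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,):
            raise ValidationError(f"weights must have length {n}")
        if (self.weights < 0).any():
            raise ParameterError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ParameterError("weights must not all be zero")
        self.weights = self.weights / total
        self.benefit_mask = np.asarray(self.benefit_mask, dtype=bool)
        if self.benefit_mask.shape != (n,):
            raise ValidationError(f"benefit_mask must have length {n}")
        if not self.alternative_names:
            self.alternative_names = [f"A{i + 1}" for i in range(m)]
        if not self.criterion_names:
            self.criterion_names = [f"C{j + 1}" for j in range(n)]
        if len(self.alternative_names) != m or len(self.criterion_names) != n:
            raise ValidationError("name lists inconsistent with matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def normalized(self) -> np.ndarray:
        """Column-wise unit-Euclidean-norm matrix (all-zero columns stay zero)."""
        norms = np.sqrt((self.x**2).sum(axis=0))
        safe = np.where(norms == 0, 1.0, norms)
        return self.x / safe

    def weighted_normalized(self) -> np.ndarray:
        return self.normalized() * self.weights


@dataclass
class ClosenessResult:
    """Per-alternative TOPSIS outputs."""

    ideal: np.ndarray  # A+ : per-criterion best weighted-normalized value
    anti_ideal: np.ndarray  # A- : per-criterion worst value
    dist_ideal: np.ndarray  # P+ : Euclidean distance to A+
    dist_anti_ideal: np.ndarray  # P- : Euclidean distance to A-
    closeness: np.ndarray  # H in [0, 1], higher is better
    order: np.ndarray  # alternatives by descending H, index tie-break


def build_decision_matrix(
    rankings: list[RankingResult],
    weights: np.ndarray | None = None,
    score_mode: str = "rank",
) -> DecisionMatrix:
    """Assemble the features-x-methods decision matrix from rankings.

    ``score_mode="rank"`` (default) enters the rank-derived benefit score
    ``m - r_ij + 1`` for feature i under method j (``r_ij`` = 1 for that
    method's best feature).  ``score_mode="raw"`` enters each method's
    native scores instead, preserving the score *spacing* that the rank
    transform discards (infinite scores are clamped just beyond the
    finite extremes of their column).  Column-wise vector normalization
    makes either choice scale-free.
    """
    if score_mode not in ("rank", "raw"):
        raise ParameterError(f"unknown score_mode {score_mode!r}")
    if not rankings:
        raise ValidationError("at least one ranking is required")
    m = rankings[0].n_features
    names = rankings[0].feature_names
    for r in rankings:
        if r.n_features != m or r.feature_names != names:
            raise ConsistencyError(
                f"ranking {r.method_name!r} covers a different feature set"
            )
    n = len(rankings)
    x = np.empty((m, n))
    for j, r in enumerate(rankings):
        if score_mode == "raw":
            col = np.empty(m)
            col[r.ordered_features] = r.scores
            col = _clamp_infinite(col)
        else:
            ranks = np.empty(m)
            ranks[r.ordered_features] = np.arange(1, m + 1)
            col = m - ranks + 1
        x[:, j] = col
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    return DecisionMatrix(
        x=x,
        weights=w,
        benefit_mask=np.ones(n, dtype=bool),
        alternative_names=list(names) if names else [],
        criterion_names=[r.method_name for r in rankings],
    )


def _clamp_infinite(col: np.ndarray) -> np.ndarray:
    """Map +/-inf scores just beyond the finite extremes of the column."""
    finite = np.isfinite(col)
    if finite.all():
        return col
    if not finite.any():
        return np.sign(col)
    lo, hi = col[finite].min(), col[finite].max()
    span = (hi - lo) or max(abs(hi), 1.0)
    out = col.copy()
    out[np.isposinf(col)] = hi + span
    out[np.isneginf(col)] = lo - span
    return out


def topsis_closeness(dm: DecisionMatrix) -> ClosenessResult:
    """Run the normalization/ideal/distance/closeness steps on ``dm``.

    Degenerate alternatives with P+ = P- = 0 (identical to every other
    alternative under every criterion) get H = 0.5, being equidistant
    from both ideals.
    """
    v = dm.weighted_normalized()
    ideal = np.where(dm.benefit_mask, v.max(axis=0), v.min(axis=0))
    anti = np.where(dm.benefit_mask, v.min(axis=0), v.max(axis=0))
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    total = d_plus + d_minus
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(total == 0, 0.5, d_minus / np.where(total == 0, 1.0, total))
    order = np.lexsort((np.arange(h.size), -h))
    return ClosenessResult(
        ideal=ideal,
        anti_ideal=anti,
        dist_ideal=d_plus,
        dist_anti_ideal=d_minus,
        closeness=h,
        order=order,
    )


def frmt_rank(
    data: ExpressionDataset,
    n_bins: int = DEFAULT_N_BINS,
    weights: np.ndarray | None = None,
    top_k: int | None = None,
    beta: float = DEFAULT_MIFS_BETA,
    rankings: list[RankingResult] | None = None,
    score_mode: str = "raw",
) -> RankingResult:
    """Fuse the ten filter rankings into one via TOPSIS closeness.

    ``rankings`` may be supplied to aggregate a custom criterion set
    (e.g. in tests); otherwise all ten methods are run.  ``top_k`` is
    recorded for report truncation only — the returned ranking is full
    depth with scores equal to the closeness H.

    The decision matrix is built from the methods' native scores
    (``score_mode="raw"``) by default: the rank transform, while simpler,
    discards how decisively a method separates features, and in
    simulation that loss measurably degrades both recovery of planted
    discriminative features and the stability of the fused top-k.
    Pass ``score_mode="rank"`` for the rank-transformed variant.
    """
    if top_k is None:
        top_k = min(10, data.n_features)
    if not 1 <= top_k <= data.n_features:
        raise ParameterError(
            f"top_k must be in [1, {data.n_features}], got {top_k}"
        )
    if rankings is None:
        rankings = rank_all_methods(data, n_bins=n_bins, beta=beta)
    dm = build_decision_matrix(rankings, weights=weights, score_mode=score_mode)
    res = topsis_closeness(dm)
    return RankingResult(
        method_name="frmt",
        ordered_features=res.order,
        scores=res.closeness[res.order],
        params={
            "n_bins": n_bins,
            "beta": beta,
            "top_k": top_k,
            "weights": dm.weights.tolist(),
            "criteria": [r.method_name for r in rankings],
            "matrix_entries": score_mode,
        },
        feature_names=list(data.feature_names),
    )
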