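"""Discretization and plug-in information-theoretic estimators (bits).

All estimators are maximum-likelihood ("plug-in") on the empirical joint
distribution, with base-2 logarithms, and clamp tiny negative values
arising from floating error to zero.  They operate on
:class:`DiscreteVector` category codes; continuous features are turned
into codes by :func:`discretize`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ParameterError, ShapeError

_NEG_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteVector:
    """Integer category codes in ``[0, n_categories)``."""

    codes: np.ndarray
    n_categories: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size == 0:
            raise ShapeError("codes must be a non-empty 1-d vector")
        if self.n_categories < 1:
            raise ParameterError("n_categories must be >= 1")
        if codes.min() < 0 or codes.max() >= self.n_categories:
            raise ShapeError("codes out of range [0, n_categories)")

    def __len__(self) -> int:
        return self.codes.size

    @classmethod
    def from_codes(cls, codes) -> "DiscreteVector":
        """Build from arbitrary integer codes, compacting to 0..K-1."""
        codes = np.asarray(codes)
        _, compact = np.unique(codes, return_inverse=True)
        k = int(compact.max()) + 1 if compact.size else 1
        return cls(compact.astype(np.int64), k)


def discretize(
    values, n_bins: int, strategy: str = "equal_frequency"
) -> DiscreteVector:
    """Bin a continuous vector into at most ``n_bins`` categories.

    ``equal_frequency`` uses empirical quantile boundaries (duplicates
    merged); ``equal_width`` uses a uniform grid over the data range.  A
    constant vector yields a single category under either strategy.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ShapeError("values must be a non-empty 1-d vector")
    if not np.isfinite(values).all():
        raise ParameterError("values must be finite")

    lo, hi = values.min(), values.max()
    if lo == hi:
        return DiscreteVector(np.zeros(values.size, dtype=np.int64), 1)

    if strategy == "equal_frequency":
        qs = np.arange(1, n_bins) / n_bins
        edges = np.unique(np.quantile(values, qs))
    elif strategy == "equal_width":
        edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    else:
        raise ParameterError(f"unknown discretization strategy {strategy!r}")

    # side="left" gives right-closed bins (the qcut convention), so a
    # heavily tied value sitting on a quantile edge stays in the lower bin
    codes = np.searchsorted(edges, values, side="left")
    return DiscreteVector.from_codes(codes)


def _check_lengths(*vs: DiscreteVector) -> int:
    n = len(vs[0])
    for v in vs[1:]:
        if len(v) != n:
            raise ShapeError(f"length mismatch: {len(v)} vs {n}")
    return n


def _entropy_from_counts(counts: np.ndarray) -> float:
    # Sorting makes the float summation order depend only on the multiset
    # of counts, so every estimate is exactly invariant to category
    # relabeling and to the order variables were product-coded in.
    counts = np.sort(counts[counts > 0])
    n = counts.sum()
    p = counts / n
    h = float(-(p * np.log2(p)).sum())
    return 0.0 if h < _NEG_TOL else h


def joint_counts(*vs: DiscreteVector) -> np.ndarray:
    """Flattened contingency counts of the product-coded variables."""
    _check_lengths(*vs)
    code = np.zeros(len(vs[0]), dtype=np.int64)
    size = 1
    for v in vs:
        code = code * v.n_categories + v.codes
        size *= v.n_categories
    return np.bincount(code, minlength=size)


def merge(*vs: DiscreteVector) -> DiscreteVector:
    """Product-code several variables into one (for joint quantities)."""
    _check_lengths(*vs)
    code = np.zeros(len(vs[0]), dtype=np.int64)
    for v in vs:
        code = code * v.n_categories + v.codes
    return DiscreteVector.from_codes(code)


def entropy(x: DiscreteVector) -> float:
    """Plug-in Shannon entropy H(X) in bits."""
    return _entropy_from_counts(joint_counts(x))


def joint_entropy(*vs: DiscreteVector) -> float:
    """Plug-in joint entropy H(X1,...,Xk) in bits."""
    return _entropy_from_counts(joint_counts(*vs))


def mutual_information(x: DiscreteVector, y: DiscreteVector) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), clamped at zero."""
    _check_lengths(x, y)
    i = entropy(x) + entropy(y) - joint_entropy(x, y)
    return max(i, 0.0)


def conditional_mutual_information(
    x: DiscreteVector, y: DiscreteVector, z: DiscreteVector
) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z), clamped at zero."""
    _check_lengths(x, y, z)
    i = (
        joint_entropy(x, z)
        + joint_entropy(y, z)
        - entropy(z)
        - joint_entropy(x, y, z)
    )
    return max(i, 0.0)


def joint_mutual_information(
    x: DiscreteVector, z: DiscreteVector, y: DiscreteVector
) -> float:
    """I(X,Z;Y): mutual information between the merged pair (X,Z) and Y."""
    _check_lengths(x, z, y)
    i = joint_entropy(x, z) + entropy(y) - joint_entropy(x, z, y)
    return max(i, 0.0)
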