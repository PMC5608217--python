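"""Labeled expression-matrix data model and delimited-text I/O.

The central type is :class:`ExpressionDataset`: a samples x features
continuous matrix with a binary class label per sample.  Labels are
encoded at load time as ``+1`` (positive class, e.g. early stage) and
``-1`` (negative class, e.g. advanced stage); every downstream module
sees only this encoding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    ConfigurationError,
    ParseError,
    ValidationError,
)

POSITIVE = 1
NEGATIVE = -1


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping emitted by :func:`load_expression_dataset`."""

    n_rows_read: int
    n_rows_dropped: int
    class_counts: dict[int, int]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_rows_dropped} row(s) dropped; "
            f"class counts: +1={self.class_counts.get(POSITIVE, 0)}, "
            f"-1={self.class_counts.get(NEGATIVE, 0)}"
        )


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with binary labels.

    Parameters
    ----------
    matrix:
        Float array of shape ``(n_samples, n_features)``; no NaN/inf.
    labels:
        Integer array of ``+1``/``-1`` per sample.
    feature_names:
        Unique names, one per column.
    sample_ids:
        Unique identifiers, one per row.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be 2-dimensional")
        n, p = self.matrix.shape
        if self.labels.shape != (n,):
            raise ValidationError(
                f"labels length {self.labels.shape} does not match {n} samples"
            )
        if len(self.feature_names) != p:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature names must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids must be unique")
        if not np.isfinite(self.matrix).all():
            raise ValidationError("matrix contains missing or non-finite values")
        bad = set(np.unique(self.labels)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValidationError(f"labels must be +1/-1, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(positive count, negative count)."""
        return (
            int(np.sum(self.labels == POSITIVE)),
            int(np.sum(self.labels == NEGATIVE)),
        )

    def require_two_classes(self, min_per_class: int = 2) -> None:
        pos, neg = self.class_counts
        if pos < min_per_class or neg < min_per_class:
            raise ValidationError(
                f"need >= {min_per_class} samples per class, got (+1: {pos}, -1: {neg})"
            )

    def subset_samples(self, index: np.ndarray) -> "ExpressionDataset":
        """Dataset restricted to the given sample positions (order kept)."""
        index = np.asarray(index)
        return ExpressionDataset(
            matrix=self.matrix[index],
            labels=self.labels[index],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in index],
        )

    def subset_features(self, index: Sequence[int]) -> "ExpressionDataset":
        idx = list(index)
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            labels=self.labels.copy(),
            feature_names=[self.feature_names[i] for i in idx],
            sample_ids=list(self.sample_ids),
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names, index=self.sample_ids)
        df.insert(0, label_column, self.labels)
        return df


@dataclass
class RankingResult:
    """Full ordering of features produced by one ranker.

    ``ordered_features`` is a permutation of ``range(n_features)``, best
    first; ``scores`` is aligned to it.  For score-based methods the
    scores are non-increasing; for greedy methods they are the criterion
    value at the step each feature was selected.
    """

    method_name: str
    ordered_features: np.ndarray
    scores: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.ordered_features = np.asarray(self.ordered_features, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        m = self.ordered_features.size
        if self.scores.shape != (m,):
            raise ValidationError("scores must align with ordered_features")
        if sorted(self.ordered_features.tolist()) != list(range(m)):
            raise ValidationError("ordered_features must be a permutation")
        if self.feature_names is not None and len(self.feature_names) != m:
            raise ValidationError("feature_names length mismatch")

    @property
    def n_features(self) -> int:
        return self.ordered_features.size

    def top(self, k: int) -> np.ndarray:
        return self.ordered_features[:k]

    def ordered_names(self) -> list[str]:
        if self.feature_names is None:
            return [f"f{i}" for i in self.ordered_features]
        return [self.feature_names[i] for i in self.ordered_features]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankingResult):
            return NotImplemented
        return (
            self.method_name == other.method_name
            and np.array_equal(self.ordered_features, other.ordered_features)
            and np.array_equal(self.scores, other.scores)
            and self.params == other.params
            and self.feature_names == other.feature_names
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_expression_dataset(
    path: str | Path,
    label_column: str,
    positive_label: str,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    Rows with missing expression values are dropped (and counted in the
    load report); a non-numeric cell is an error naming its row/column.
    All labels other than ``positive_label`` map to the negative class.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found in {path.name}; "
            f"columns: {list(df.columns)[:10]}"
        )
    n_read = len(df)
    labels_raw = df[label_column]
    expr = df.drop(columns=[label_column])

    values = np.empty(expr.shape, dtype=float)
    missing = np.zeros(expr.shape, dtype=bool)
    for j, col in enumerate(expr.columns):
        for i, cell in enumerate(expr[col]):
            s = cell.strip()
            if s == "" or s.upper() in {"NA", "NAN", "NULL"}:
                missing[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(s)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i + 2} "
                    f"(file line), column {col!r}"
                ) from None

    keep = ~missing.any(axis=1)
    n_dropped = int((~keep).sum())
    values = values[keep]
    labels_kept = labels_raw[keep]

    labels = np.where(labels_kept.str.strip() == positive_label, POSITIVE, NEGATIVE)
    sample_ids = [f"S{i}" for i in np.flatnonzero(keep)]

    counts = {
        POSITIVE: int(np.sum(labels == POSITIVE)),
        NEGATIVE: int(np.sum(labels == NEGATIVE)),
    }
    if counts[POSITIVE] < 2 or counts[NEGATIVE] < 2:
        raise ValidationError(
            f"each class needs >= 2 samples after load; got {counts} "
            f"(positive label {positive_label!r})"
        )
    report = LoadReport(n_rows_read=n_read, n_rows_dropped=n_dropped, class_counts=counts)
    return ExpressionDataset(
        matrix=values,
        labels=labels,
        feature_names=list(expr.columns),
        sample_ids=sample_ids,
        load_report=report,
    )


def write_expression_dataset(
    data: ExpressionDataset, path: str | Path, label_column: str = "label"
) -> None:
    """Write the dataset back to CSV/TSV (separator chosen by extension)."""
    path = Path(path)
    df = data.to_dataframe(label_column)
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_ranking(result: RankingResult, path: str | Path) -> None:
    """Serialize a ranking as TSV plus a ``.json`` provenance sidecar.

    The TSV has columns ``rank``, ``feature_name``, ``score``; the
    sidecar records the method name, every parameter, and the feature
    index order so that :func:`read_ranking` round-trips losslessly.
    """
    if result.n_features == 0:
        raise ValidationError("cannot write an empty ranking")
    path = Path(path)
    names = result.ordered_names()
    with open(path, "w") as fh:
        fh.write("rank\tfeature_name\tscore\n")
        for r, (name, score) in enumerate(zip(names, result.scores), start=1):
            fh.write(f"{r}\t{name}\t{score!r}\n")
    sidecar = {
        "method_name": result.method_name,
        "params": _jsonable(result.params),
        "ordered_features": result.ordered_features.tolist(),
        "scores": [float(s) for s in result.scores],
        "feature_names": result.feature_names,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_ranking(path: str | Path) -> RankingResult:
    """Inverse of :func:`write_ranking` (reads the sidecar for exactness)."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return RankingResult(
        method_name=sidecar["method_name"],
        ordered_features=np.array(sidecar["ordered_features"], dtype=int),
        scores=np.array(sidecar["scores"], dtype=float),
        params=sidecar["params"],
        feature_names=sidecar["feature_names"],
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
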