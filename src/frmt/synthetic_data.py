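"""Generator of two-class expression matrices with planted structure.

Emulates the statistical shape of a reverse-phase protein-array cohort:
continuous, roughly Gaussian within-class feature values, a handful of
truly discriminative proteins (class-mean shift in SD units), optional
correlated copies of those proteins, and realistic class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ParameterError
from .io_core import NEGATIVE, POSITIVE, ExpressionDataset

#: Class counts (positive/early, negative/advanced) of seven cohorts.
PRESET_CLASS_COUNTS: dict[str, tuple[int, int]] = {
    "READ": (60, 62),
    "HSNE": (48, 152),
    "LUSC": (158, 35),
    "COAD": (187, 139),
    "OV": (33, 370),
    "UCEC": (321, 83),
    "KIRC": (263, 190),
}

#: Per-preset planted effect sizes for the benchmark suite (SD units).
_SUITE_EFFECT_SIZES: dict[str, float] = {
    "READ": 1.5,
    "HSNE": 1.2,
    "LUSC": 1.0,
    "COAD": 0.9,
    "OV": 0.8,
    "UCEC": 0.6,
    "KIRC": 0.5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset."""

    n_early: int
    n_advanced: int
    n_features: int = 115
    n_informative: int = 0
    effect_size: float = 1.0
    n_redundant: int = 0
    redundancy_rho: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_early < 2 or self.n_advanced < 2:
            raise ParameterError("each class needs >= 2 samples")
        if self.n_features < 1:
            raise ParameterError("n_features must be positive")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ParameterError("counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ParameterError(
                "n_informative + n_redundant must not exceed n_features"
            )
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ParameterError("redundant features need informative parents")
        if not 0.0 < self.redundancy_rho < 1.0:
            raise ParameterError("redundancy_rho must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Which columns carry signal in a generated dataset."""

    informative: tuple[int, ...]
    redundant: tuple[int, ...]
    parents: dict[int, int] = field(default_factory=dict)  # redundant -> parent


def generate(config: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset: null features i.i.d. N(0,1) per class, informative
    features shifted by ``effect_size`` in the early class, redundant
    features correlated ``redundancy_rho`` with an informative parent."""
    rng = np.random.default_rng(config.seed)
    n = config.n_early + config.n_advanced
    p = config.n_features
    labels = np.concatenate(
        [np.full(config.n_early, POSITIVE), np.full(config.n_advanced, NEGATIVE)]
    )
    matrix = rng.standard_normal((n, p))

    informative = tuple(range(config.n_informative))
    matrix[: config.n_early, list(informative)] += config.effect_size

    redundant = tuple(
        range(config.n_informative, config.n_informative + config.n_redundant)
    )
    parents: dict[int, int] = {}
    rho = config.redundancy_rho
    for offset, col in enumerate(redundant):
        parent = informative[offset % len(informative)]
        parents[col] = parent
        noise = rng.normal(0.0, config.noise_sd, size=n)
        matrix[:, col] = rho * matrix[:, parent] + np.sqrt(1 - rho**2) * noise

    data = ExpressionDataset(
        matrix=matrix,
        labels=labels,
        feature_names=[f"P{j + 1}" for j in range(p)],
        sample_ids=[f"S{i + 1}" for i in range(n)],
    )
    return data, GroundTruth(informative, redundant, parents)


def preset_config(
    preset: str,
    seed: int = 0,
    n_features: int = 115,
    n_informative: int = 8,
    effect_size: float | None = None,
    n_redundant: int = 0,
    redundancy_rho: float = 0.8,
) -> SyntheticConfig:
    """Config with class counts copied from a named cohort preset."""
    if preset not in PRESET_CLASS_COUNTS:
        raise ParameterError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESET_CLASS_COUNTS)}"
        )
    n_early, n_advanced = PRESET_CLASS_COUNTS[preset]
    if effect_size is None:
        effect_size = _SUITE_EFFECT_SIZES[preset]
    return SyntheticConfig(
        n_early=n_early,
        n_advanced=n_advanced,
        n_features=n_features,
        n_informative=n_informative,
        effect_size=effect_size,
        n_redundant=n_redundant,
        redundancy_rho=redundancy_rho,
        seed=seed,
    )


def benchmark_suite(
    seed: int = 0,
    n_redundant: int = 8,
) -> list[tuple[str, ExpressionDataset, GroundTruth]]:
    """Seven datasets mirroring the cohort class counts (2101 samples in
    total), each with 115 features, 8 informative at effect sizes from
    1.5 down to 0.5, plus a correlated redundant block."""
    suite = []
    for i, preset in enumerate(PRESET_CLASS_COUNTS):
        cfg = preset_config(preset, seed=seed + i, n_redundant=n_redundant)
        data, truth = generate(cfg)
        suite.append((preset, data, truth))
    return suite
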