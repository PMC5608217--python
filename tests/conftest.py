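import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from frmt import ExpressionDataset, SyntheticConfig, generate

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 samples x 3 features, balanced classes, deterministic values."""
    return ExpressionDataset(
        matrix=np.array(
            [
                [1.0, 10.0, 0.5],
                [2.0, 11.0, 0.4],
                [5.0, 10.5, 0.6],
                [6.0, 9.5, 0.5],
            ]
        ),
        labels=np.array([1, 1, -1, -1]),
        feature_names=["fa", "fb", "fc"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def planted_dataset():
    """60+60 samples, 20 features, 4 informative at a strong effect."""
    cfg = SyntheticConfig(
        n_early=60,
        n_advanced=60,
        n_features=20,
        n_informative=4,
        effect_size=1.8,
        seed=7,
    )
    return generate(cfg)
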