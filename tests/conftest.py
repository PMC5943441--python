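import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_network(rng: np.random.Generator, n: int):
    """Random valid CorrelationNetwork on n genes (generic weights, no ties)."""
    from pathproxy import CorrelationNetwork

    w = rng.uniform(0.01, 0.99, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return CorrelationNetwork([f"g{i:02d}" for i in range(n)], w)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr():
    """3 genes x 4 samples with two groups of two."""
    from pathproxy import ExpressionMatrix, GroupDesign

    expr = ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 1.0, 3.0, 3.0], [2.0, 4.0, 2.0, 4.0], [5.0, 5.0, 5.0, 5.0]]),
    )
    design = GroupDesign({"s1": "ctrl", "s2": "ctrl", "s3": "can", "s4": "can"})
    return expr, design
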