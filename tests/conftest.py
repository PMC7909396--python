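import numpy as np
import pytest

from halfsam import LabeledExpressionMatrix


@pytest.fixture
def hand_matrix():
    """One gene: case {2,2,4,4}, control {0,0,2,2} (hand-checkable moments)."""
    return LabeledExpressionMatrix(
        values=[[2.0, 2.0, 4.0, 4.0, 0.0, 0.0, 2.0, 2.0]],
        gene_ids=["gA"],
        labels=[1, 1, 1, 1, 0, 0, 0, 0],
    )


@pytest.fixture
def random_matrix():
    """60 genes x (5 case + 7 control) of lognormal-ish intensities."""
    rng = np.random.default_rng(42)
    values = np.exp(rng.normal(5.0, 1.0, (60, 12)))
    return LabeledExpressionMatrix(
        values=values, labels=[1] * 5 + [0] * 7,
        gene_ids=[f"g{i:03d}" for i in range(60)],
    )


@pytest.fixture
def tiny_matrix():
    """5 genes x (3 case + 3 control): exhaustively permutable."""
    rng = np.random.default_rng(7)
    values = rng.normal(0.0, 1.0, (5, 6))
    values[0, :3] += 4.0  # one clearly shifted gene
    return LabeledExpressionMatrix(values=values, labels=[1, 1, 1, 0, 0, 0])
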