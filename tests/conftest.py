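import numpy as np
import pytest

from panelboost import ExpressionMatrix, LabelVector, SimulationConfig, simulate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(9)],
        values=rng.normal(5.0, 1.0, size=(6, 9)),
    )


@pytest.fixture
def tiny_labels() -> LabelVector:
    return LabelVector(
        sample_ids=[f"s{j}" for j in range(9)],
        labels=["A"] * 3 + ["B"] * 3 + ["C"] * 3,
    )


@pytest.fixture
def easy_dataset():
    """Well-separated three-class dataset with 5 planted genes."""
    return simulate(
        SimulationConfig(
            p=60, n_per_class=20, n_informative=5, effect=3.0, block_size=5, seed=5
        )
    )
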