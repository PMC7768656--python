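import numpy as np
import pytest

from exprshape.data import AnalysisConfig, ExpressionMatrix, Scale, SurvivalTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Pipeline config with a small bootstrap for quick unit tests."""
    return AnalysisConfig(rng_seed=7, n_bootstrap=49, n_trees=50, n_repeats=3,
                          n_selected_genes=5)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["A", "B"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        Scale.LOG2,
    )


@pytest.fixture
def small_survival():
    return SurvivalTable(
        ["A", "B", "C", "D"],
        np.array([10.0, 20.0, 30.0, 40.0]),
        np.array([1, 0, 1, 1]),
        np.array([80.0, 60.0, np.nan, 90.0]),
    )
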