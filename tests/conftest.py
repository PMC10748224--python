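import numpy as np
import pandas as pd
import pytest

from hrrnet.expression import ExpressionMatrix
from hrrnet.synthetic import StageDesign, default_truth, generate_dataset


def toy_matrix(rows, stages=("A", "B"), reps=2):
    """Build an ExpressionMatrix from {gene: [values in sample order]}."""
    cols = [f"{s}_{r}" for s in stages for r in range(1, reps + 1)]
    return ExpressionMatrix(
        pd.DataFrame(rows, index=cols).T.astype(float), tuple(stages)
    )


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard synthetic benchmark (seed 1), generated once per session."""
    truth = default_truth(seed=1)
    design = StageDesign()
    matrix, deg, annot, tfs = generate_dataset(truth, design)
    return truth, design, matrix, deg, annot, tfs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
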