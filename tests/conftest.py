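import numpy as np
import pandas as pd
import pytest

from fshdmbb.data_io import ExpressionMatrix, Signature


@pytest.fixture
def rng():
    return np.random.default_rng(20230816)


@pytest.fixture
def small_matrix():
    """3 genes x 2 samples, log scale, with annotations."""
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=["GENE1", "GENE2", "GENE3"],
    )
    ann = pd.DataFrame(
        {
            "cohort": ["c", "c"],
            "tissue": ["muscle", "muscle"],
            "tirm": ["neg", "neg"],
            "group": ["fshd", "control"],
            "subject_id": ["p1", "p2"],
        },
        index=["s1", "s2"],
    )
    return ExpressionMatrix(values, samples=ann)


@pytest.fixture
def random_matrix(rng):
    """20 genes x 12 samples of log-normal-ish expression."""
    values = pd.DataFrame(
        7 + rng.standard_normal((20, 12)),
        index=[f"G{i:02d}" for i in range(20)],
        columns=[f"S{j:02d}" for j in range(12)],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def two_arm_signature():
    return Signature("sig", ("G00", "G01", "G02", "G03"), ("G04", "G05", "G06"))
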