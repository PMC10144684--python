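import numpy as np
import pandas as pd
import pytest

from coclin import ExpressionMatrix, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic co-clinical cohort."""
    return make_cohort(n_patients=6, n_pdx=4, n_genes=300, n_planted=10, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-scale cohort: 21 patients, 9 PDX."""
    return make_cohort(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def expr_10x5(rng):
    """10 genes x 5 samples of log-normal counts."""
    values = pd.DataFrame(
        rng.lognormal(4.0, 1.0, size=(10, 5)),
        index=[f"G{i}" for i in range(10)],
        columns=[f"S{j}" for j in range(5)],
    )
    return ExpressionMatrix(values)
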