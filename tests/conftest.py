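import numpy as np
import pandas as pd
import pytest

from tensorcog import SyntheticSpec, make_regression_problem
from tensorcog.preprocess_io import LongitudinalCohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(rows, biomarkers=("b1", "b2", "b3")):
    """Build a cohort from (patient, visit, date, group, values...) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "visit_code", "exam_date", "group",
                                     *biomarkers])
    df["exam_date"] = pd.to_datetime(df["exam_date"])
    return LongitudinalCohort(df, tuple(biomarkers))


@pytest.fixture(scope="session")
def small_problem():
    """One-interval synthetic regression problem reused across model tests."""
    spec = SyntheticSpec(n=40, d=10, rank=2, seed=7)
    return make_regression_problem(spec)


@pytest.fixture(scope="session")
def random_tensor():
    """Symmetric zero-diagonal nonnegative (8, 8, 12) tensor stack."""
    rng = np.random.default_rng(99)
    X = rng.random((8, 8, 12))
    X = (X + X.transpose(1, 0, 2)) / 2
    for k in range(12):
        np.fill_diagonal(X[:, :, k], 0.0)
    return X
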