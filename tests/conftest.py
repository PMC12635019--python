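import numpy as np
import pandas as pd
import pytest

from clockaudit.io import BetaMatrix, ClockModel
from clockaudit.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Mid-size mixed cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(n_samples=500, disease_fraction=0.3, seed=7))


@pytest.fixture(scope="session")
def big_cohort():
    """Larger healthy-only cohort for Monte-Carlo correlation checks."""
    return generate_cohort(CohortSpec(n_samples=2000, disease_fraction=0.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def hand_model():
    """The 4-CpG arithmetic-oracle model."""
    return ClockModel(name="hand", intercept=0.0,
                      coefficients={"cg1": 1.0, "cg2": -1.0,
                                    "cg3": 2.0, "cg4": -0.5})


@pytest.fixture
def hand_stats():
    """Univariate correlations paired with :func:`hand_model`."""
    return pd.DataFrame({"pearson_r": [0.5, 0.5, -0.5, -0.5]},
                        index=["cg1", "cg2", "cg3", "cg4"])


def make_beta(values, sample_ids=None, cpg_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[0])]
    cpg_ids = cpg_ids or [f"cg{j + 1}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=sample_ids, columns=cpg_ids))


def make_metadata(ages, status=None, sample_ids=None) -> pd.DataFrame:
    ages = np.asarray(ages, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(len(ages))]
    status = status if status is not None else ["healthy"] * len(ages)
    return pd.DataFrame({"age": ages, "status": status},
                        index=pd.Index(sample_ids, name="sample_id"))
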