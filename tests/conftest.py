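import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import famepi as fp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_cohort() -> fp.Cohort:
    """The deterministic 947-subject reconstruction of the published
    contingency table."""
    return fp.fixture_table1()


@pytest.fixture(scope="session")
def table1_tsv(tmp_path_factory, table1_cohort):
    path = tmp_path_factory.mktemp("fixture") / "table1_cohort.tsv"
    fp.write_cohort(table1_cohort, path)
    return path


@pytest.fixture()
def tiny_cohort() -> fp.Cohort:
    """Two families of two; one SNP; hand-checkable."""
    df = pd.DataFrame(
        {
            "family_id": ["f1", "f1", "f2", "f2"],
            "subject_id": ["s1", "s2", "s3", "s4"],
            "age": [60.0, 70.0, 55.0, 65.0],
            "affected": [True, True, True, False],
            "aggressive": pd.array([True, False, pd.NA, pd.NA], dtype="boolean"),
            "rs1": ["AG", "GG", "AA", None],
        }
    )
    return fp.Cohort(data=df, snps=(fp.SnpDef("rs1", risk_allele="A"),))


def random_design(rng: np.random.Generator, n: int = 30, p: int = 3):
    """A small random full-rank Poisson design with moderate rates."""
    X = np.column_stack([np.ones(n), rng.normal(0, 0.5, size=(n, p - 1))])
    beta = rng.normal(0, 0.4, size=p)
    y = rng.poisson(np.exp(X @ beta))
    labels = tuple(["intercept"] + [f"x{j}" for j in range(1, p)])
    return fp.DesignResponse(X=X, y=y, labels=labels, kept_rows=np.arange(n))
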