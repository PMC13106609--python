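import numpy as np
import pandas as pd
import pytest

import heliotol as ht


@pytest.fixture(scope="session")
def cohort():
    """Default 48-genotype synthetic cohort, fixed seed."""
    return ht.generate_cohort(seed=20260929)


@pytest.fixture(scope="session")
def means(cohort):
    return ht.aggregate_replicates(cohort.table)


@pytest.fixture(scope="session")
def tolerance_matrix(means):
    return ht.tolerance_coefficients(means)


@pytest.fixture(scope="session")
def printed_ci():
    """The published comprehensive-index values for the 48 accessions."""
    df = ht.load_fixture("ci_ranking")
    return pd.Series(df["ci"].to_numpy(), index=df["code"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
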