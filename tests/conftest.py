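import numpy as np
import pandas as pd
import pytest

from defcnv import default_catalogue
from defcnv.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def cohort():
    """One seeded study-like cohort shared by read-only tests."""
    return simulate_cohort(default_config(seed=20240901, n_samples=100))


@pytest.fixture(scope="session")
def expected_cn_map(cohort):
    return {g.assay_group: float(g.expected_cn) for g in cohort.config.genes}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Hand-sized count matrix with a reference gene for formula checks."""
    return pd.DataFrame(
        {
            "GENE1": [100, 200, 300],
            "GENE2": [50, 100, 150],
            "TP53": [1000, 2000, 3000],
        },
        index=["s1", "s2", "s3"],
    )
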