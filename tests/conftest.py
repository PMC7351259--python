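import numpy as np
import pytest

from snpbarcode.core import Barcode
from snpbarcode.dataset import CohortMatrix, builtin_snp_table, generate_cohort


@pytest.fixture(scope="session")
def snp_table():
    return builtin_snp_table()


@pytest.fixture(scope="session")
def small_cohort(snp_table):
    """A 200-per-group cohort from the packaged table (fast to search)."""
    return generate_cohort(snp_table, n_per_group=200, seed=1)


@pytest.fixture(scope="session")
def full_cohort(snp_table):
    """The study-sized 5000/5000 cohort regenerated from the packaged table."""
    return generate_cohort(snp_table, n_per_group=5000, seed=0)


@pytest.fixture
def toy_matrix():
    """Four samples, two SNPs: 2 cases match (1, 2), 1 control matches, 1 not."""
    genotypes = np.array(
        [
            [1, 2],  # case, matches
            [1, 2],  # case, matches
            [1, 2],  # control, matches
            [3, 2],  # control, no match
        ],
        dtype=np.int8,
    )
    labels = np.array([True, True, False, False])
    return CohortMatrix(genotypes=genotypes, labels=labels)


@pytest.fixture
def toy_barcode():
    return Barcode((1, 2), (1, 2))


def random_matrix(rng, n_samples=30, n_snps=5):
    genotypes = rng.integers(1, 4, size=(n_samples, n_snps)).astype(np.int8)
    labels = rng.random(n_samples) < 0.5
    return CohortMatrix(genotypes=genotypes, labels=labels)
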