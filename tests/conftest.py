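import numpy as np
import pytest

from founderpop.data_model import MISSING, GenotypeMatrix


def make_genotypes(
    calls,
    populations=None,
    fragment_ids=None,
    individual_ids=None,
    snp_ids=None,
):
    """Build a GenotypeMatrix from a nested list with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix(
        individual_ids=individual_ids or [f"i{k}" for k in range(n)],
        snp_ids=snp_ids or [f"s{j}" for j in range(m)],
        fragment_ids=fragment_ids or [f"f{j}" for j in range(m)],
        populations=populations or ["pop1"] * n,
        calls=calls,
    )


@pytest.fixture
def toy_genotypes():
    """3 individuals x 2 SNPs, one missing call."""
    return make_genotypes([[0, 1], [1, 2], [2, MISSING]])


@pytest.fixture(scope="session")
def fixture_dataset():
    """The default three-river simulated dataset (shared, read-only)."""
    from founderpop.synthetic_data import default_config, simulate_dataset

    return simulate_dataset(default_config(seed=7))
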