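import pytest

from aaopt.aaindex_io import CANONICAL_ALPHABET, FeatureRecord, FeatureTable
from aaopt.synthetic import generate_planted_table


@pytest.fixture(scope="session")
def alphabet():
    return CANONICAL_ALPHABET


def record_from_values(values, accession="TEST00001", alphabet=CANONICAL_ALPHABET):
    """A FeatureRecord whose values follow alphabet order."""
    return FeatureRecord(
        accession=accession, values=dict(zip(alphabet, map(float, values)))
    )


@pytest.fixture()
def ascending_record():
    """Values 1..20 assigned in alphabet order (A=1 ... V=20)."""
    return record_from_values(range(1, 21))


@pytest.fixture(scope="session")
def planted():
    """A balanced planted table (20 residues, 3 noise features)."""
    return generate_planted_table(n_residues=20, n_noise_features=3, seed=7)


@pytest.fixture()
def single_record_table(ascending_record):
    return FeatureTable(alphabet=CANONICAL_ALPHABET, records=[ascending_record])
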