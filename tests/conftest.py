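import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pepforge import (
    Dataset,
    PeptideRecord,
    SyntheticSpec,
    generate,
    load_property_table,
)
from pepforge.alphabet import AMINO_ACIDS

PRINTED_PEPTIDE = "GLWSKIKEVGKEAAKAAAKAAGKAALGAVSEAV"


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture
def printed_record():
    """The sample record printed in the benchmark corpus documentation."""
    return PeptideRecord(id="ACP_1", sequence=PRINTED_PEPTIDE, label="ACP")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_peptides(rng, n, length_range=(10, 50), prefix="pep"):
    """Uniform-composition random peptide records."""
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n):
        L = int(rng.integers(*length_range, endpoint=True))
        seq = "".join(alphabet[rng.integers(0, 20, size=L)])
        records.append(PeptideRecord(id=f"{prefix}_{i}", sequence=seq))
    return records


@pytest.fixture
def random_dataset(rng):
    return Dataset(records=tuple(random_peptides(rng, 50)), name="random")


@pytest.fixture(scope="session")
def small_two_class():
    """A small well-separated synthetic dataset for classifier tests."""
    return generate(SyntheticSpec(n_acp=60, n_nacp=60, effect_size=3.0, seed=7, name="small"))
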