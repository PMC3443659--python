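import numpy as np
import pytest

from dmkcluster import FamilyModel, TupleAlphabet, generate_families


@pytest.fixture(scope="session")
def alphabet2() -> TupleAlphabet:
    return TupleAlphabet(2)


@pytest.fixture(scope="session")
def alphabet3() -> TupleAlphabet:
    return TupleAlphabet(3)


@pytest.fixture(scope="session")
def four_families():
    """Balanced 4-family synthetic set: 20 seqs/family, 1000 bp, 2%
    substitution — the clean parameter-recovery baseline."""
    model = FamilyModel(
        n_families=4,
        seqs_per_family=(20, 20, 20, 20),
        ancestor_lengths=(1000, 1000, 1000, 1000),
        substitution_rate=0.02,
        seed=11,
    )
    return generate_families(model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
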