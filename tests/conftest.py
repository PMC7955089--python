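import numpy as np
import pytest

import mutgan as mg


@pytest.fixture(scope="session")
def dna():
    return mg.dna_alphabet()


@pytest.fixture(scope="session")
def donor_dataset():
    """Small balanced donor-window dataset (length 15)."""
    spec = mg.CompositionSpec(counts={"DP": 60, "DN": 60}, seed=7)
    return mg.generate_nn269_mimic(spec)


@pytest.fixture(scope="session")
def acceptor_dataset():
    """Small balanced acceptor-window dataset (length 90)."""
    spec = mg.CompositionSpec(counts={"AP": 12, "AN": 12}, seed=7)
    return mg.generate_nn269_mimic(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_mutator():
    """Small untrained generator over a 3-letter alphabet, full fill vocab."""
    alphabet = mg.build_alphabet(("a", "b", "c"))
    return mg.SequenceMutator(
        alphabet=alphabet, embed_dim=8, where_hidden=(4, 4), where_dense=4,
        replace_hidden=(6, 6), attn_hidden=4, exclude_source=False,
        random_state=5).fit()
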