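import numpy as np
import pytest

from pairqsar.synthetic import toy_molecule_suite


@pytest.fixture(scope="session")
def toy_suite():
    """Parsed, typed, charged toy molecules with oracle golden values."""
    return toy_molecule_suite()


@pytest.fixture(scope="session")
def toy_by_smiles(toy_suite):
    return {smi: (g, golden) for smi, g, golden in toy_suite}


@pytest.fixture()
def rng():
    return np.random.default_rng(20220725)
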