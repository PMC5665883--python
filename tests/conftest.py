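import numpy as np
import pytest
from hypothesis import settings

from enrichbench import LibrarySpec, gen_ligand_library

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library50():
    """Small synthetic ligand library with activity annotations."""
    return gen_ligand_library(LibrarySpec(n=50, seed=7))


@pytest.fixture(scope="session")
def library100():
    return gen_ligand_library(LibrarySpec(n=100, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
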