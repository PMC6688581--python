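import numpy as np
import pytest

from rnaffinity import GBRTConfig
from rnaffinity.fixtures import ToyComplexSpec, make_toy_complex
from rnaffinity.protein_features import ResiduePropertyTable


@pytest.fixture(scope="session")
def prop_table() -> ResiduePropertyTable:
    return ResiduePropertyTable.default()


@pytest.fixture(scope="session")
def small_gbrt() -> GBRTConfig:
    """Ensemble sized for the small synthetic problems used in tests."""
    return GBRTConfig(n_trees=20, max_depth=2, shrinkage=0.2)


@pytest.fixture()
def toy_files():
    """One deterministic synthetic complex with all four canned tool files."""
    return make_toy_complex(ToyComplexSpec(n_protein_residues=35, n_rna_nt=12,
                                           seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
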