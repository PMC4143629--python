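import numpy as np
import pytest

from pedscore.pedstruct import Pedigree
from pedscore.simkit import replicate_pedigrees, three_generation_pedigree


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([
        ("f1", "F", "", "", "male"),
        ("f1", "M", "", "", "female"),
        ("f1", "C", "F", "M", "female"),
    ])


@pytest.fixture
def family16() -> Pedigree:
    """One template three-generation family of 16."""
    return three_generation_pedigree("fam1")


@pytest.fixture
def sample160() -> Pedigree:
    """Ten template families, 160 individuals."""
    return replicate_pedigrees(10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
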