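import numpy as np
import pytest

from glycomhc.glycodb import GlycanLimits, build_default_glycan_db
from glycomhc.sequence_space import (ModConfig, build_peptide_index,
                                     enumerate_nonspecific_peptides,
                                     make_decoys)
from glycomhc.synthetic import generate_proteome


@pytest.fixture(scope="session")
def small_glycan_db():
    """Compact database (HexNAc<=3, Hex<=4, Fuc<=1, NeuAc<=1) for fast tests."""
    limits = GlycanLimits(max_counts=(("HexNAc", 3), ("Hex", 4), ("Fuc", 1),
                                      ("NeuAc", 1), ("NeuGc", 0)),
                          min_mass=145.0, max_mass=3000.0)
    return build_default_glycan_db(limits)


@pytest.fixture(scope="session")
def default_glycan_db():
    return build_default_glycan_db()


@pytest.fixture(scope="session")
def tiny_proteome():
    proteins, truth = generate_proteome(n_proteins=6, length=90,
                                        sequon_density=0.03, seed=11)
    return proteins, truth


@pytest.fixture(scope="session")
def tiny_index(tiny_proteome):
    proteins, _ = tiny_proteome
    everything = proteins + make_decoys(proteins)
    candidates = enumerate_nonspecific_peptides(everything, (7, 25))
    index = build_peptide_index(candidates, ModConfig(False, False, False, 0))
    return candidates, index


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
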