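import numpy as np
import pytest

from psmlod.chem import DEFAULT_TABLE
from psmlod.database import enumerate_modified_forms
from psmlod.simulate import SimulationConfig, generate_database, simulate_spectra

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def table():
    return DEFAULT_TABLE


def random_sequence(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))


def make_peptide(sequence, **kwargs):
    """Unmodified Peptide object for a bare sequence."""
    (pep,) = enumerate_modified_forms(sequence, (), **kwargs)
    return pep


@pytest.fixture(scope="session")
def small_proteome():
    """A tiny deterministic proteome with its target index (no mods)."""
    cfg = SimulationConfig(seed=11, n_proteins=30, protein_length_range=(80, 160))
    fasta, index = generate_database(cfg, max_missed=0, min_length=6, max_length=25)
    return cfg, fasta, index


@pytest.fixture(scope="session")
def noiseless_sims(small_proteome):
    """Noiseless spectra simulated from 25 peptides of the small proteome."""
    cfg, _fasta, index = small_proteome
    rng = np.random.default_rng(7)
    picks = [index.records[int(i)] for i in rng.integers(0, len(index), size=25)]
    return simulate_spectra(cfg, picks)
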