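import warnings

import numpy as np
import pytest

from spanr import (
    NoesySimParams, SynthParams, find_potential_contacts, make_corpus,
    make_fold, make_shift_table, simulate_noesy,
)

warnings.filterwarnings("ignore", message=".*could not be anchored.*")


@pytest.fixture(scope="session")
def hairpin20():
    """A 20-residue hairpin fold used across modules."""
    return make_fold(SynthParams(n_resi=20, topology="hairpin", geom_seed=7))


@pytest.fixture(scope="session")
def hairpin20_shifts(hairpin20):
    return make_shift_table(hairpin20, seed=11)


@pytest.fixture(scope="session")
def hairpin20_peaks(hairpin20, hairpin20_shifts):
    return simulate_noesy(hairpin20, hairpin20_shifts, NoesySimParams(seed=13))


@pytest.fixture(scope="session")
def hairpin20_contacts(hairpin20_peaks, hairpin20_shifts):
    return find_potential_contacts(hairpin20_peaks, hairpin20_shifts)


@pytest.fixture(scope="session")
def corpus300():
    """The 300-member synthetic corpus used by the acceptance suite."""
    return make_corpus(SynthParams(corpus_size=300, geom_seed=2024,
                                   shift_seed=2025))


ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  H   ALA A   1      -0.500  -0.870   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def ala_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(ALA_PDB)
    return p
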