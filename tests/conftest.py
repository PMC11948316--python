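import numpy as np
import pytest

from linkdock import ChainPair, FixtureSpec, fuse, make_native
from linkdock.structure import ComplexModel, Residue


@pytest.fixture
def toy_pair():
    return ChainPair("rec", "ACDEF", "pep", "KLM")


@pytest.fixture
def small_native():
    """A 60+10 residue synthetic complex with its sequence pair."""
    return make_native(FixtureSpec(receptor_length=60, peptide_length=10, seed=11))


def single_atom_model(rec_positions, pep_positions, pep_plddt=None):
    """Minimal complex: one CA atom per residue at the given coordinates."""
    pep_plddt = pep_plddt or [70.0] * len(pep_positions)
    receptor = [
        Residue(i + 1, "A", {"CA": np.asarray(p, float)}, 90.0)
        for i, p in enumerate(rec_positions)
    ]
    peptide = [
        Residue(i + 1, "K", {"CA": np.asarray(p, float)}, q)
        for i, (p, q) in enumerate(zip(pep_positions, pep_plddt))
    ]
    return ComplexModel(receptor=receptor, peptide=peptide)
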