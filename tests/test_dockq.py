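import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from linkdock import (
    DegenerateGeometryError,
    FixtureSpec,
    ValidationError,
    classify,
    dockq_score,
    evaluate,
    fnat,
    irmsd,
    kabsch_superpose,
    lrmsd,
    make_decoy,
    make_native,
)
from linkdock.dockq import native_interface_residues
from linkdock.errors import EvaluationError
from linkdock.structure import ComplexModel, Residue

from .oracles import brute_contacts, quaternion_superpose


# --- Kabsch superposition ---------------------------------------------------

def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    rot, trans, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(rot, np.eye(3), atol=1e-10)
    assert np.allclose(trans, 0.0, atol=1e-10)


def test_kabsch_recovers_known_rigid_motion():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 3))
    true_rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
    moved = pts @ true_rot.T + np.array([1.0, -2.0, 3.0])
    rot, trans, rmsd = kabsch_superpose(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(rot, true_rot, atol=1e-9)
    assert np.linalg.det(rot) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_kabsch_matches_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    moving = rng.normal(scale=5, size=(10, 3))
    reference = rng.normal(scale=5, size=(10, 3))
    _, _, rmsd = kabsch_superpose(moving, reference)
    _, _, rmsd_q = quaternion_superpose(moving, reference)
    assert rmsd == pytest.approx(rmsd_q, abs=1e-6)


def test_kabsch_degenerate_inputs_rejected():
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, line)


# --- FNAT -------------------------------------------------------------------

def eight_contact_native():
    """Eight isolated receptor/peptide residue pairs, each 3 A apart: exactly
    eight native cross-chain contacts at the 5 A cutoff."""
    receptor = [
        Residue(i + 1, "A", {"CA": np.array([0.0, 0.0, i * 30.0])}, 90.0)
        for i in range(8)
    ]
    peptide = [
        Residue(i + 1, "K", {"CA": np.array([3.0, 0.0, i * 30.0])}, 90.0)
        for i in range(8)
    ]
    return ComplexModel(receptor=receptor, peptide=peptide)


def test_fnat_examples():
    native = eight_contact_native()
    assert fnat(native, native) == 1.0

    # break exactly half of the 8 native contacts
    half = eight_contact_native()
    for res in half.peptide[4:]:
        res.atoms["CA"] = res.atoms["CA"] + np.array([50.0, 0.0, 0.0])
    assert fnat(half, native) == 0.5

    far = eight_contact_native()
    for res in far.peptide:
        res.atoms["CA"] = res.atoms["CA"] + np.array([50.0, 0.0, 0.0])
    assert fnat(far, native) == 0.0


def test_fnat_contacts_match_bruteforce(small_native):
    native, _ = small_native
    from linkdock.dockq import _contact_pairs

    got = _contact_pairs(native.receptor, native.peptide, 5.0)
    assert got == brute_contacts(native.receptor, native.peptide, 5.0)


def test_fnat_rejects_contactless_native():
    native = eight_contact_native()
    for res in native.peptide:
        res.atoms["CA"] = res.atoms["CA"] + np.array([100.0, 0.0, 0.0])
    with pytest.raises(EvaluationError, match="no cross-chain contacts"):
        fnat(eight_contact_native(), native)


def test_mismatched_sequences_rejected(small_native):
    native, _ = small_native
    mutant, _ = make_native(FixtureSpec(receptor_length=60, peptide_length=10, seed=99))
    with pytest.raises(EvaluationError, match="correspondence"):
        fnat(mutant, native)


# --- LRMSD / iRMSD ----------------------------------------------------------

def test_lrmsd_identity_and_translation(small_native):
    native, _ = small_native
    assert lrmsd(native, native) == pytest.approx(0.0, abs=1e-9)
    decoy = make_decoy(native, displacement=5.0)
    assert lrmsd(decoy, native) == pytest.approx(5.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_lrmsd_matches_independent_two_step_oracle(seed, small_native):
    """Superpose receptors with the quaternion oracle, then measure peptide RMSD."""
    native, _ = small_native
    rng = np.random.default_rng(seed)
    decoy = make_decoy(native, displacement=rng.uniform(1, 10),
                       rotation=tuple(rng.uniform(-40, 40, 3)),
                       noise_sigma=0.3, seed=seed)

    backbone = ("N", "CA", "C", "O")
    mod_rec = np.array([r.atoms[a] for r in decoy.receptor for a in backbone])
    nat_rec = np.array([r.atoms[a] for r in native.receptor for a in backbone])
    rot, trans, _ = quaternion_superpose(mod_rec, nat_rec)
    mod_pep = np.array([r.atoms[a] for r in decoy.peptide for a in backbone])
    nat_pep = np.array([r.atoms[a] for r in native.peptide for a in backbone])
    moved = mod_pep @ rot.T + trans
    expected = float(np.sqrt(np.mean(np.sum((moved - nat_pep) ** 2, axis=1))))
    assert lrmsd(decoy, native) == pytest.approx(expected, abs=1e-6)


def test_irmsd_identity_and_interface_set(small_native):
    native, _ = small_native
    assert irmsd(native, native) == pytest.approx(0.0, abs=1e-9)
    rec_iface, pep_iface = native_interface_residues(native, 10.0)
    brute = brute_contacts(native.receptor, native.peptide, 10.0)
    assert rec_iface == {r for r, _ in brute}
    assert pep_iface == {p for _, p in brute}


def test_irmsd_sensitive_to_interface_only_perturbation(small_native):
    native, _ = small_native
    decoy = make_decoy(native, displacement=2.0)
    # receptor untouched: superposing receptors alone is exact
    backbone = ("N", "CA", "C", "O")
    mod_rec = np.array([r.atoms[a] for r in decoy.receptor for a in backbone])
    nat_rec = np.array([r.atoms[a] for r in native.receptor for a in backbone])
    _, _, rec_rmsd = kabsch_superpose(mod_rec, nat_rec)
    assert rec_rmsd == pytest.approx(0.0, abs=1e-9)
    assert irmsd(decoy, native) > 0.5


# --- DockQ combination and classification ------------------------------------

def test_dockq_analytic_points():
    assert dockq_score(1.0, 0.0, 0.0) == 1.0
    assert dockq_score(0.5, 1.5, 8.5) == pytest.approx(0.5)
    assert dockq_score(0.0, 1e6, 1e6) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_dockq_monotonicity(seed):
    rng = np.random.default_rng(seed)
    f, i, l = rng.uniform(0, 1), rng.uniform(0, 20), rng.uniform(0, 20)
    base = dockq_score(f, i, l)
    assert dockq_score(min(f + 0.1, 1.0), i, l) >= base
    assert dockq_score(f, i + 1.0, l) <= base
    assert dockq_score(f, i, l + 1.0) <= base


def test_classification_boundaries():
    assert classify(0.22) == "incorrect"
    assert classify(0.23) == "acceptable"
    assert classify(0.25) == "acceptable"
    assert classify(0.5) == "medium"
    assert classify(0.8) == "high"
    assert classify(1.0) == "high"
    with pytest.raises(ValidationError):
        classify(1.2)


@pytest.mark.parametrize("seed", [0, 7, 42])
def test_native_self_evaluation_is_perfect(seed):
    native, _ = make_native(FixtureSpec(receptor_length=30, peptide_length=6, seed=seed))
    result = evaluate(native, native)
    assert result.fnat == 1.0
    assert result.irmsd == pytest.approx(0.0, abs=1e-9)
    assert result.lrmsd == pytest.approx(0.0, abs=1e-9)
    assert result.dockq == pytest.approx(1.0)
    assert result.category == "high"
    # stored category is consistent with the combination formula
    assert classify(dockq_score(result.fnat, result.irmsd, result.lrmsd)) == result.category
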