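import json

import numpy as np
import pytest

from linkdock import (
    FixtureSpec,
    RankingScheme,
    ValidationError,
    assign_plddt,
    decoy_at_distance,
    evaluate,
    fnat,
    is_docked,
    lrmsd,
    make_decoy,
    make_native,
    mean_peptide_plddt,
    min_interchain_distance,
    rank_and_select,
    read_pdb,
    write_pdb,
)
from linkdock.fixtures import (
    PLDDT_ANTICORRELATED,
    PLDDT_CONTACT_CORRELATED,
    PLDDT_UNIFORM,
    decoy_pool,
    write_fixture_set,
)
from linkdock.ranking import MEAN_PEPTIDE


def test_native_is_deterministic_and_in_contact():
    spec = FixtureSpec(receptor_length=40, peptide_length=8, seed=3)
    a, pair_a = make_native(spec)
    b, pair_b = make_native(spec)
    assert pair_a == pair_b
    for ra, rb in zip(a.all_residues(), b.all_residues()):
        for name in ra.atoms:
            assert np.array_equal(ra.atoms[name], rb.atoms[name])
    assert min_interchain_distance(a) == pytest.approx(4.0, abs=1e-6)


def test_single_residue_peptide_is_valid():
    native, pair = make_native(FixtureSpec(receptor_length=20, peptide_length=1, seed=0))
    assert len(native.peptide) == 1
    assert len(pair.peptide_seq) == 1
    assert evaluate(native, native).dockq == pytest.approx(1.0)


def test_invalid_specs_rejected():
    with pytest.raises(ValidationError):
        FixtureSpec(receptor_length=2)
    with pytest.raises(ValidationError):
        FixtureSpec(peptide_length=0)
    with pytest.raises(ValidationError):
        FixtureSpec(coordinate_noise_sigma=-1)


def test_identity_decoy_scores_perfect(small_native):
    native, _ = small_native
    decoy = make_decoy(native, displacement=0.0)
    assert evaluate(decoy, native).dockq == pytest.approx(1.0)


def test_far_displaced_decoy(small_native):
    native, _ = small_native
    decoy = make_decoy(native, displacement=50.0)
    assert fnat(decoy, native) == 0.0
    assert not is_docked(decoy)


@pytest.mark.parametrize("displacement", [1.0, 5.0, 12.5])
def test_translation_decoy_lrmsd_matches_provenance(small_native, displacement):
    """For a pure rigid translation the recorded transform predicts LRMSD exactly."""
    native, _ = small_native
    decoy = make_decoy(native, displacement=displacement)
    assert lrmsd(decoy, native) == pytest.approx(displacement, abs=1e-6)
    recorded = np.linalg.norm(decoy.provenance["true_translation"])
    assert lrmsd(decoy, native) == pytest.approx(recorded, abs=1e-6)


@pytest.mark.parametrize("distance", [3.0, 7.0, 8.0, 12.0, 30.0])
def test_decoy_at_distance_calibration(small_native, distance):
    native, _ = small_native
    decoy = decoy_at_distance(native, distance, rotation=(10, -20, 5), noise_sigma=0.3)
    assert min_interchain_distance(decoy) == pytest.approx(distance, abs=1e-6)


def test_assign_plddt_modes(small_native):
    native, _ = small_native
    uniform = assign_plddt(native, PLDDT_UNIFORM, uniform_value=70.0)
    assert all(r.plddt == 70.0 for r in uniform.all_residues())

    docked = decoy_at_distance(native, 5.0)
    undocked = decoy_at_distance(native, 20.0)
    for seed in range(5):
        corr_docked = assign_plddt(docked, PLDDT_CONTACT_CORRELATED, seed=seed)
        assert 75.0 <= mean_peptide_plddt(corr_docked) <= 95.0
        corr_undocked = assign_plddt(undocked, PLDDT_CONTACT_CORRELATED, seed=seed)
        assert 20.0 <= mean_peptide_plddt(corr_undocked) <= 50.0
        anti_docked = assign_plddt(docked, PLDDT_ANTICORRELATED, seed=seed)
        assert 20.0 <= mean_peptide_plddt(anti_docked) <= 50.0
        anti_undocked = assign_plddt(undocked, PLDDT_ANTICORRELATED, seed=seed)
        assert 75.0 <= mean_peptide_plddt(anti_undocked) <= 95.0
        # receptor confidence stays high in every mode
        assert all(r.plddt >= 75.0 for r in corr_docked.receptor)


def test_pdb_roundtrip_at_coordinate_precision(tmp_path, small_native):
    native, _ = small_native
    path = tmp_path / "fixture.pdb"
    write_pdb(native, path)
    again = read_pdb(path)
    for ra, rb in zip(native.all_residues(), again.all_residues()):
        for name, xyz in ra.atoms.items():
            assert np.allclose(np.round(xyz, 3), rb.atoms[name], atol=5e-4)


def test_anticorrelated_confidence_fools_mean_peptide_but_not_contact_weighting():
    """Stress test over seeded pools where confidence anti-correlates with
    docking correctness: detached decoys carry high pLDDT, docked ones low.
    The mean-peptide scheme chases the high-confidence detached decoys; the
    contact-weighted scheme is structurally immune because detached peptides
    score zero regardless of confidence, so its pick is never worse and is
    strictly better whenever a pool offers both a contacting and a detached
    decoy."""
    strictly_better, mixed_pools = 0, 0
    n_pools = 50
    for seed in range(n_pools):
        spec = FixtureSpec(receptor_length=40, peptide_length=8, seed=1000 + seed)
        native, decoys = decoy_pool(spec, n_decoys=8, dock_fraction=0.5,
                                    plddt_mode=PLDDT_ANTICORRELATED, seed=seed)
        qs = [evaluate(d, native).dockq for d in decoys]
        by_mean = rank_and_select(decoys, RankingScheme(name=MEAN_PEPTIDE))
        by_weighted = rank_and_select(decoys, RankingScheme())
        q_mean = qs[by_mean[0].variant_index]
        q_weighted = qs[by_weighted[0].variant_index]
        assert q_weighted >= q_mean
        has_contacting = any(min_interchain_distance(d) <= 5.0 for d in decoys)
        has_detached = any(min_interchain_distance(d) > 8.0 for d in decoys)
        if has_contacting and has_detached:
            mixed_pools += 1
            strictly_better += q_weighted > q_mean
    assert mixed_pools >= 0.5 * n_pools
    assert strictly_better == mixed_pools


def test_write_fixture_set(tmp_path):
    specs = [FixtureSpec(receptor_length=20, peptide_length=5, seed=s) for s in (0, 1)]
    out = write_fixture_set(tmp_path / "fixtures", specs)
    manifest = json.loads((out / "manifest.json").read_text())
    assert len(manifest) == 2
    for entry in manifest:
        native = read_pdb(out / f"{entry['target']}_native.pdb")
        assert evaluate(native, native).dockq == pytest.approx(
            entry["expected_self_dockq"], abs=1e-6
        )
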