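"""CAPRI-style docking quality: FNAT, iRMSD, LRMSD combined into DockQ.

For a model/native pair of two-chain complexes (receptor chain A, peptide
chain B, residues paired by chain and residue number):

* FNAT — fraction of native cross-chain residue contacts (any heavy-atom pair
  within 5 A) that the model preserves;
* LRMSD — peptide (ligand) backbone RMSD after superposing the model receptor
  backbone onto the native receptor;
* iRMSD — backbone RMSD over the native interface residues (both chains, 10 A
  heavy-atom definition) after superposing on those residues;
* DockQ — the continuous combination

      DockQ = ( FNAT + 1/(1+(iRMSD/1.5)^2) + 1/(1+(LRMSD/8.5)^2) ) / 3

  with the community-standard scale constants 1.5 A and 8.5 A, classified as
  incorrect [0, 0.23), acceptable [0.23, 0.5), medium [0.5, 0.8), high [0.8, 1].

Superpositions use the Kabsch algorithm (SVD of the cross-covariance with a
determinant correction so the rotation is always proper).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, EvaluationError, ValidationError
from .structure import ComplexModel, Residue

logger = logging.getLogger(__name__)

FNAT_CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
IRMSD_SCALE = 1.5
LRMSD_SCALE = 8.5
BACKBONE = ("N", "CA", "C", "O")

CATEGORY_THRESHOLDS = (
    (0.80, "high"),
    (0.50, "medium"),
    (0.23, "acceptable"),
    (0.00, "incorrect"),
)


@dataclass(frozen=True)
class DockQResult:
    """CAPRI metrics and the combined DockQ score for one model/native pair."""

    fnat: float
    irmsd: float
    lrmsd: float
    dockq: float
    category: str


def kabsch_superpose(moving: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``moving`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps moving points onto the reference with
    minimal RMSD; the rotation is proper (det = +1).
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValidationError("superposition requires two equal-shape (n, 3) arrays")
    n = len(moving)
    if n < 3:
        raise DegenerateGeometryError(f"superposition needs >= 3 points, got {n}")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(reference))):
        raise ValidationError("superposition input contains non-finite coordinates")

    mov_c = moving - moving.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # Collinear point sets leave a rotation axis unconstrained.
    if (np.linalg.matrix_rank(mov_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2):
        raise DegenerateGeometryError("collinear point set: superposition is ambiguous")

    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = reference.mean(axis=0) - rotation @ moving.mean(axis=0)
    moved = moving @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def _pair_chains(model_chain: list[Residue], native_chain: list[Residue],
                 chain_label: str) -> list[tuple[Residue, Residue]]:
    """Pair residues by residue number; identities must agree (X is a wildcard)."""
    by_number = {r.number: r for r in model_chain}
    pairs = []
    for nat in native_chain:
        mod = by_number.get(nat.number)
        if mod is None:
            continue
        if "X" not in (mod.aa, nat.aa) and mod.aa != nat.aa:
            raise EvaluationError(
                f"chain {chain_label} residue {nat.number}: model {mod.aa} vs "
                f"native {nat.aa} — correspondence requires identical sequences"
            )
        pairs.append((mod, nat))
    return pairs


def _correspondence(model: ComplexModel, native: ComplexModel):
    rec = _pair_chains(model.receptor, native.receptor, "A")
    pep = _pair_chains(model.peptide, native.peptide, "B")
    if not rec or not pep:
        raise EvaluationError("no residue correspondence between model and native")
    return rec, pep


def _heavy(res: Residue) -> np.ndarray:
    return res.atom_coords("heavy_atoms")


def _contact_pairs(receptor: list[Residue], peptide: list[Residue],
                   cutoff: float) -> set[tuple[int, int]]:
    """Cross-chain residue pairs with any heavy-atom distance <= cutoff."""
    contacts = set()
    rec_coords = [( r.number, _heavy(r)) for r in receptor]
    pep_coords = [(p.number, _heavy(p)) for p in peptide]
    for rn, rxyz in rec_coords:
        for pn, pxyz in pep_coords:
            if len(rxyz) and len(pxyz) and cdist(rxyz, pxyz).min() <= cutoff:
                contacts.add((rn, pn))
    return contacts


def fnat(model: ComplexModel, native: ComplexModel,
         contact_cutoff: float = FNAT_CONTACT_CUTOFF) -> float:
    """Fraction of native cross-chain contacts preserved by the model."""
    _correspondence(model, native)
    native_contacts = _contact_pairs(native.receptor, native.peptide, contact_cutoff)
    if not native_contacts:
        raise EvaluationError(
            "native complex has no cross-chain contacts at "
            f"{contact_cutoff} A — malformed reference"
        )
    model_contacts = _contact_pairs(model.receptor, model.peptide, contact_cutoff)
    return len(native_contacts & model_contacts) / len(native_contacts)


def _backbone_arrays(pairs: list[tuple[Residue, Residue]], context: str):
    """Matched backbone coordinate arrays for paired residues.

    Residues missing any of N/CA/C/O are dropped with a warning; evaluation
    fails when more than 10% of the expected atoms are missing.
    """
    mod_pts, nat_pts = [], []
    dropped = 0
    for mod, nat in pairs:
        if all(a in mod.atoms for a in BACKBONE) and all(a in nat.atoms for a in BACKBONE):
            for a in BACKBONE:
                mod_pts.append(mod.atoms[a])
                nat_pts.append(nat.atoms[a])
        else:
            dropped += 1
            logger.warning("%s: residue %d lacks full backbone; dropped", context, nat.number)
    if dropped > 0.1 * len(pairs):
        raise EvaluationError(
            f"{context}: {dropped}/{len(pairs)} residues lack backbone atoms"
        )
    if not mod_pts:
        raise EvaluationError(f"{context}: no usable backbone atoms")
    return np.array(mod_pts), np.array(nat_pts)


def lrmsd(model: ComplexModel, native: ComplexModel) -> float:
    """Peptide backbone RMSD after superposing the receptors."""
    rec_pairs, pep_pairs = _correspondence(model, native)
    mod_rec, nat_rec = _backbone_arrays(rec_pairs, "receptor")
    rotation, translation, _ = kabsch_superpose(mod_rec, nat_rec)
    mod_pep, nat_pep = _backbone_arrays(pep_pairs, "peptide")
    moved = mod_pep @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - nat_pep) ** 2, axis=1))))


def native_interface_residues(native: ComplexModel,
                              interface_cutoff: float = INTERFACE_CUTOFF):
    """Residue numbers (receptor set, peptide set) of the native interface."""
    contacts = _contact_pairs(native.receptor, native.peptide, interface_cutoff)
    rec = {rn for rn, _ in contacts}
    pep = {pn for _, pn in contacts}
    return rec, pep


def irmsd(model: ComplexModel, native: ComplexModel,
          interface_cutoff: float = INTERFACE_CUTOFF) -> float:
    """Backbone RMSD over native interface residues after interface superposition."""
    rec_pairs, pep_pairs = _correspondence(model, native)
    rec_iface, pep_iface = native_interface_residues(native, interface_cutoff)
    if not rec_iface and not pep_iface:
        raise EvaluationError("native complex has an empty interface")
    pairs = [(m, n) for m, n in rec_pairs if n.number in rec_iface]
    pairs += [(m, n) for m, n in pep_pairs if n.number in pep_iface]
    mod_pts, nat_pts = _backbone_arrays(pairs, "interface")
    _, _, rmsd = kabsch_superpose(mod_pts, nat_pts)
    return rmsd


def dockq_score(fnat_value: float, irmsd_value: float, lrmsd_value: float) -> float:
    """Combine FNAT, iRMSD and LRMSD into the DockQ score in [0, 1]."""
    if not 0.0 <= fnat_value <= 1.0:
        raise ValidationError(f"fnat {fnat_value} outside [0, 1]")
    if irmsd_value < 0 or lrmsd_value < 0:
        raise ValidationError("RMSD values must be nonnegative")
    return (
        fnat_value
        + 1.0 / (1.0 + (irmsd_value / IRMSD_SCALE) ** 2)
        + 1.0 / (1.0 + (lrmsd_value / LRMSD_SCALE) ** 2)
    ) / 3.0


def classify(dockq: float) -> str:
    """Quality category for a DockQ value (left-closed bins)."""
    if not 0.0 <= dockq <= 1.0:
        raise ValidationError(f"DockQ {dockq} outside [0, 1]")
    for threshold, label in CATEGORY_THRESHOLDS:
        if dockq >= threshold:
            return label
    return "incorrect"


ACCEPTABLE_OR_BETTER = ("acceptable", "medium", "high")


def evaluate(model: ComplexModel, native: ComplexModel) -> DockQResult:
    """Full CAPRI/DockQ evaluation of a model against its native complex."""
    f = fnat(model, native)
    i = irmsd(model, native)
    l = lrmsd(model, native)
    q = dockq_score(f, i, l)
    return DockQResult(fnat=f, irmsd=i, lrmsd=l, dockq=q, category=classify(q))
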