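"""Post-processing of fused predictions and interchain geometry primitives.

A predictor sees the fused receptor-linker-peptide chain as one polypeptide.
After prediction the linker is excised and the remaining residues are split
into a two-chain complex: receptor as chain A and peptide as chain B, each
renumbered from 1. All contact and docking decisions downstream are phrased as
minimum interatomic distances between the two chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError

HEAVY_ATOMS = "heavy_atoms"
BACKBONE_ONLY = "backbone_only"
CALPHA_ONLY = "calpha_only"

_BACKBONE = ("N", "CA", "C", "O")

#: Peptides further than this from the receptor are considered misdocked.
DOCK_CUTOFF = 8.0


@dataclass
class Residue:
    """One residue: number within its chain, one-letter code, atoms, confidence."""

    number: int
    aa: str
    atoms: dict[str, np.ndarray]
    plddt: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValidationError(f"pLDDT {self.plddt} outside [0, 100]")
        for name, xyz in self.atoms.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValidationError(f"atom {name} has non-finite coordinates")
            self.atoms[name] = xyz

    def atom_coords(self, policy: str = HEAVY_ATOMS) -> np.ndarray:
        """Coordinates of this residue's atoms under an atom-selection policy."""
        if policy == HEAVY_ATOMS:
            names = [n for n in self.atoms if not n.strip().upper().startswith("H")]
        elif policy == BACKBONE_ONLY:
            names = [n for n in _BACKBONE if n in self.atoms]
        elif policy == CALPHA_ONLY:
            names = ["CA"] if "CA" in self.atoms else []
        else:
            raise ValidationError(f"unknown atom policy {policy!r}")
        return np.array([self.atoms[n] for n in names]).reshape(-1, 3)


@dataclass
class ComplexModel:
    """Two-chain protein-peptide model: receptor chain A, peptide chain B.

    Residues are numbered from 1 within each chain; per-residue pLDDT is kept
    (written to the B-factor column on PDB output). ``provenance`` records how
    the model was produced (variant index, seed, recycles used, true decoy
    transform for synthetic models).
    """

    receptor: list[Residue]
    peptide: list[Residue]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.receptor or not self.peptide:
            raise ValidationError("both chains of a complex model must be nonempty")

    def all_residues(self) -> list[Residue]:
        return list(self.receptor) + list(self.peptide)

    def mean_plddt(self) -> float:
        """Mean pLDDT over all residues of both chains."""
        return float(np.mean([r.plddt for r in self.all_residues()]))


def _chain_coords(chain: list[Residue], policy: str):
    coords, owners = [], []
    for res in chain:
        xyz = res.atom_coords(policy)
        if len(xyz) == 0:
            continue
        coords.append(xyz)
        owners.extend([res.number] * len(xyz))
    if not coords:
        raise ValidationError(f"chain has no atoms under policy {policy!r}")
    return np.concatenate(coords), np.array(owners)


def split_and_excise(predicted, spans: dict[str, tuple[int, int]],
                     sequence: str | None = None) -> ComplexModel:
    """Cut a fused single-chain prediction into a two-chain complex.

    Residues inside the linker span are discarded; receptor residues become
    chain A (renumbered 1..R) and peptide residues chain B (1..P), with
    coordinates and pLDDT carried over unchanged. ``sequence`` optionally
    supplies the unmasked fused sequence so that residues hidden behind the
    mask placeholder recover their true identity.

    ``predicted`` is any object with an ordered ``residues`` attribute of
    :class:`Residue`-like records (the predictor-backend output).
    """
    residues = list(predicted.residues)
    span_values = [spans[k] for k in ("receptor", "linker", "peptide")]
    covered = sorted(span_values)
    if covered[0][0] != 0 or covered[-1][1] != len(residues) or any(
        a[1] != b[0] for a, b in zip(covered, covered[1:])
    ):
        raise ValidationError(
            f"segment spans {spans} do not partition a structure of length {len(residues)}"
        )
    if sequence is not None and len(sequence) != len(residues):
        raise ValidationError("reference sequence length does not match the structure")

    def carve(span: tuple[int, int]) -> list[Residue]:
        out = []
        for new_number, i in enumerate(range(*span), start=1):
            src = residues[i]
            aa = sequence[i] if sequence is not None else src.aa
            out.append(Residue(new_number, aa, dict(src.atoms), src.plddt))
        return out

    return ComplexModel(
        receptor=carve(spans["receptor"]),
        peptide=carve(spans["peptide"]),
        provenance=dict(getattr(predicted, "provenance", {})),
    )


def min_interchain_distance(model: ComplexModel, atom_policy: str = HEAVY_ATOMS) -> float:
    """Minimum cross-chain atom-pair distance under the atom policy."""
    rec, _ = _chain_coords(model.receptor, atom_policy)
    pep, _ = _chain_coords(model.peptide, atom_policy)
    return float(cdist(rec, pep).min())


def contacting_peptide_residues(model: ComplexModel, cutoff: float) -> set[int]:
    """Peptide residue numbers with any heavy atom within ``cutoff`` of the receptor."""
    if cutoff <= 0:
        raise ValidationError(f"contact cutoff must be positive, got {cutoff}")
    rec, _ = _chain_coords(model.receptor, HEAVY_ATOMS)
    pep, owners = _chain_coords(model.peptide, HEAVY_ATOMS)
    per_atom_min = cdist(pep, rec).min(axis=1)
    return {int(n) for n in np.unique(owners[per_atom_min <= cutoff])}


def is_docked(model: ComplexModel, cutoff: float = DOCK_CUTOFF) -> bool:
    """True when the peptide touches the receptor (min heavy-atom distance <= cutoff).

    The boundary counts as in contact: a peptide exactly at the cutoff is
    docked, only "more than cutoff away" is misdocked.
    """
    return min_interchain_distance(model, HEAVY_ATOMS) <= cutoff
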