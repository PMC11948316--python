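"""PDB reading and writing for two-chain complex models.

Models are written with the receptor as chain A and the peptide as chain B,
residues numbered from 1 per chain, TER records between chains, and per-residue
pLDDT stored in the B-factor column (the convention structure predictors use).
The reader tolerates both pre-split two-chain files and single-chain fused
files when a segment map is supplied. HETATM records and hydrogens are skipped;
alternate locations take the first conformer.
"""

from __future__ import annotations

import gemmi
import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

from .errors import ValidationError
from .structure import ComplexModel, Residue

_ONE_TO_THREE = {one: three.upper() for one, three in protein_letters_1to3.items()}
_ONE_TO_THREE["X"] = "UNK"
_THREE_TO_ONE = {three.upper(): one for three, one in protein_letters_3to1.items()}
_THREE_TO_ONE["UNK"] = "X"

_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _element_for(atom_name: str) -> str:
    name = atom_name.strip().upper()
    return _ELEMENTS.get(name, name[0] if name else "C")


def _gemmi_chain(chain_id: str, residues: list[Residue]) -> gemmi.Chain:
    chain = gemmi.Chain(chain_id)
    for res in residues:
        g_res = gemmi.Residue()
        g_res.name = _ONE_TO_THREE.get(res.aa.upper(), "UNK")
        g_res.seqid = gemmi.SeqId(res.number, " ")
        for atom_name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(_element_for(atom_name))
            atom.pos = gemmi.Position(*(float(v) for v in xyz))
            atom.b_iso = float(res.plddt)
            atom.occ = 1.0
            g_res.add_atom(atom)
        chain.add_residue(g_res)
    return chain


def write_pdb(model: ComplexModel, path) -> None:
    """Write a complex model as a two-chain PDB file (pLDDT in B-factors)."""
    structure = gemmi.Structure()
    structure.name = "linkdock model"
    gmodel = gemmi.Model("1")
    gmodel.add_chain(_gemmi_chain("A", model.receptor))
    gmodel.add_chain(_gemmi_chain("B", model.peptide))
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


def _residues_from_chain(chain: gemmi.Chain) -> list[Residue]:
    residues = []
    for g_res in chain:
        if g_res.het_flag == "H":
            continue
        atoms: dict[str, np.ndarray] = {}
        plddts = []
        for atom in g_res:
            if atom.element.is_hydrogen:
                continue
            if atom.altloc not in ("", "\0", "A"):
                continue  # first conformer only
            if atom.name in atoms:
                continue
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            plddts.append(atom.b_iso)
        if not atoms:
            continue
        aa = _THREE_TO_ONE.get(g_res.name.upper(), "X")
        residues.append(
            Residue(g_res.seqid.num, aa, atoms, float(np.mean(plddts)))
        )
    return residues


def read_pdb(path, receptor_chain: str = "A", peptide_chain: str = "B",
             spans: dict[str, tuple[int, int]] | None = None) -> ComplexModel:
    """Read a complex model from PDB.

    Two-chain files are read directly via the chain ids. A single-chain fused
    file is accepted when ``spans`` locates receptor/linker/peptide within it;
    the linker is excised and the chains renumbered exactly as in
    :func:`linkdock.structure.split_and_excise`.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    gmodel = structure[0]
    chains = {chain.name: chain for chain in gmodel}

    if spans is not None:
        if len(chains) != 1:
            raise ValidationError(
                "a segment map applies only to single-chain fused files; "
                f"found chains {sorted(chains)}"
            )
        fused = _residues_from_chain(next(iter(chains.values())))
        from .backends import PredictedStructure

        predicted = PredictedStructure(residues=[
            Residue(i, r.aa, r.atoms, r.plddt) for i, r in enumerate(fused)
        ])
        from .structure import split_and_excise

        return split_and_excise(predicted, spans)

    try:
        receptor = _residues_from_chain(chains[receptor_chain])
        peptide = _residues_from_chain(chains[peptide_chain])
    except KeyError as exc:
        raise ValidationError(
            f"chain {exc} not present in {path}; found {sorted(chains)}"
        ) from None
    return ComplexModel(receptor=receptor, peptide=peptide)
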