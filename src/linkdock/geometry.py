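"""Toy backbone geometry shared by the mock predictor and the fixture generator.

The receptor is built as an ideal alpha-helix (1.5 A rise and 100 degree twist
per residue) and the peptide as an extended segment. These are not physically
refined conformations: they exist so that every distance, contact and RMSD
operation in the pipeline has well-defined, controllable geometry. Atoms are
backbone (N, CA, C, O) plus CB for non-glycine residues; heavy-atom policies
operate on whatever atoms are present.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

HELIX_RISE = 1.5          # A per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # A, CA radial distance from the axis
EXTENDED_STEP = 3.8       # A, CA-CA distance in an extended strand

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def helix_coords(n_residues: int, sequence: str | None = None) -> list[dict[str, np.ndarray]]:
    """Backbone + CB coordinates for an ideal alpha-helix along +z.

    Returns one ``{atom_name: xyz}`` dict per residue. Glycines (when a
    sequence is supplied) carry no CB.
    """
    residues = []
    for i in range(n_residues):
        theta = np.deg2rad(HELIX_TWIST * i)
        z = HELIX_RISE * i
        ca = np.array([HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), z])
        th_n = theta - np.deg2rad(28.0)
        th_c = theta + np.deg2rad(28.0)
        n = np.array([1.6 * np.cos(th_n), 1.6 * np.sin(th_n), z - 0.9])
        c = np.array([1.7 * np.cos(th_c), 1.7 * np.sin(th_c), z + 0.8])
        o = c + np.array([0.4 * np.cos(th_c), 0.4 * np.sin(th_c), 1.1])
        atoms = {"N": n, "CA": ca, "C": c, "O": o}
        if sequence is None or sequence[i] != "G":
            atoms["CB"] = np.array(
                [3.4 * np.cos(theta), 3.4 * np.sin(theta), z + 0.5]
            )
        residues.append(atoms)
    return residues


def extended_coords(n_residues: int, sequence: str | None = None) -> list[dict[str, np.ndarray]]:
    """Backbone + CB coordinates for an extended segment along +z at the origin."""
    residues = []
    for i in range(n_residues):
        z = EXTENDED_STEP * i
        zig = 0.5 if i % 2 else -0.5
        ca = np.array([0.0, zig, z])
        atoms = {
            "N": ca + np.array([0.3, -0.9, -1.2]),
            "CA": ca,
            "C": ca + np.array([-0.3, 0.9, 1.2]),
            "O": ca + np.array([-1.4, 1.1, 1.3]),
        }
        if sequence is None or sequence[i] != "G":
            atoms["CB"] = ca + np.array([1.3, 0.8, 0.2])
        residues.append(atoms)
    return residues


def stack_atoms(residues: list[dict[str, np.ndarray]]) -> np.ndarray:
    """All atom coordinates of a residue list as an (n_atoms, 3) array."""
    return np.array([xyz for res in residues for xyz in res.values()])


def transform_residues(residues, rotation: Rotation | None = None,
                       translation: np.ndarray | None = None,
                       about: np.ndarray | None = None):
    """Apply a rigid transform (rotation about a pivot, then translation)."""
    if about is None:
        about = np.zeros(3)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    out = []
    for res in residues:
        new = {}
        for name, xyz in res.items():
            v = xyz - about
            if rotation is not None:
                v = rotation.apply(v)
            new[name] = v + about + t
        out.append(new)
    return out


def min_distance(residues_a, residues_b) -> float:
    """Minimum pairwise distance between two atom clouds."""
    return float(cdist(stack_atoms(residues_a), stack_atoms(residues_b)).min())


def place_at_min_distance(peptide, receptor, target: float,
                          direction: np.ndarray | None = None):
    """Translate ``peptide`` along ``direction`` until its minimum heavy-atom
    distance to ``receptor`` equals ``target`` (solved by root bracketing).

    The default direction points radially away from the receptor axis (+x),
    matching the canonical construction where the helix runs along +z.
    """
    if target <= 0:
        raise ValueError("target minimum distance must be positive")
    u = np.array([1.0, 0.0, 0.0]) if direction is None else np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    pep_atoms = stack_atoms(peptide)
    rec_atoms = stack_atoms(receptor)

    def gap(t: float) -> float:
        return float(cdist(pep_atoms + t * u, rec_atoms).min()) - target

    # Bracket the root by walking from the current position: outward travel
    # increases the gap, inward travel shrinks it toward a clash (gap < 0)
    # before the clouds can interpenetrate.
    if gap(0.0) < 0:
        lo, hi = 0.0, 1.0
        while gap(hi) < 0:
            hi *= 2
            if hi > 1e5:
                raise RuntimeError("failed to bracket placement root")
    else:
        lo, hi = -1.0, 0.0
        while gap(lo) > 0:
            lo *= 2
            if lo < -1e5:
                raise RuntimeError("failed to bracket placement root")
    t_star = brentq(gap, lo, hi, xtol=1e-9)
    return transform_residues(peptide, translation=t_star * u), t_star * u
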