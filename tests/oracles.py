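"""Independent brute-force oracles used to cross-check production code.

Everything here is deliberately naive (pure loops, no shared code paths with
the package's vectorized implementations): exhaustive pair scans for distances
and contacts, and Horn's quaternion method for rigid superposition as a check
on the SVD-based Kabsch implementation.
"""

from __future__ import annotations

import numpy as np


def brute_min_distance(chain_a, chain_b) -> float:
    """Minimum distance over every cross-chain atom pair, by explicit loops."""
    best = float("inf")
    for res_a in chain_a:
        for xyz_a in res_a.atoms.values():
            for res_b in chain_b:
                for xyz_b in res_b.atoms.values():
                    d = float(np.sqrt(np.sum((np.asarray(xyz_a) - np.asarray(xyz_b)) ** 2)))
                    best = min(best, d)
    return best


def brute_contacts(receptor, peptide, cutoff: float) -> set[tuple[int, int]]:
    """Cross-chain residue pairs with any atom pair within cutoff."""
    contacts = set()
    for res_r in receptor:
        for res_p in peptide:
            hit = False
            for xyz_r in res_r.atoms.values():
                for xyz_p in res_p.atoms.values():
                    if np.sqrt(np.sum((np.asarray(xyz_r) - np.asarray(xyz_p)) ** 2)) <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                contacts.add((res_r.number, res_p.number))
    return contacts


def brute_contacting_peptide(receptor, peptide, cutoff: float) -> set[int]:
    return {p for _, p in brute_contacts(receptor, peptide, cutoff)}


def quaternion_superpose(moving: np.ndarray, reference: np.ndarray):
    """Horn's closed-form quaternion solution to the rigid superposition problem.

    Returns (rotation_matrix, translation, rmsd); independent of the SVD-based
    Kabsch route it is used to validate.
    """
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)
    mc = moving.mean(axis=0)
    rc = reference.mean(axis=0)
    a = moving - mc
    b = reference - rc
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    q = eigvecs[:, -1]  # quaternion (w, x, y, z) for the largest eigenvalue
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = rc - rot @ mc
    moved = moving @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, translation, rmsd
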