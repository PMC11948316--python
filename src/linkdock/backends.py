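"""Structure-predictor contract, deterministic mock backend, adaptive recycling.

The docking protocol is predictor-agnostic: any callable that maps a
:class:`PredictionRequest` (fused sequence, recycle count, seed) to a
:class:`PredictedStructure` (per-residue coordinates + pLDDT) can drive it.
The built-in :class:`MockBackend` produces deterministic toy geometry so that
fusion, masking, recycling, post-processing, ranking and evaluation are all
testable without GPU inference.

Adaptive recycling starts at the standard 3 recycles and, while the peptide
remains more than 8 A from the receptor, reruns the prediction with the
recycle count raised in steps of 3 up to a maximum of 12.

A thin adapter for a real external predictor (a subprocess producing a PDB
file with per-residue confidence in the B-factor column, read back through
:func:`linkdock.pdbio.read_pdb`) follows the same contract; it is deliberately
outside the tested surface because it requires GPU-scale inference.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry
from .errors import ConfigurationError, PredictionError, ValidationError
from .sequences import MASK_SYMBOL
from .structure import (
    DOCK_CUTOFF,
    ComplexModel,
    Residue,
    min_interchain_distance,
    split_and_excise,
)

DEFAULT_RECYCLES = 3
MAX_RECYCLES = 12
RECYCLE_STEP = 3


@dataclass(frozen=True)
class PredictionRequest:
    """One prediction job: a (possibly masked) sequence, recycles, and a seed."""

    sequence: str
    num_recycles: int = DEFAULT_RECYCLES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_recycles < 0:
            raise ValidationError("num_recycles must be >= 0")
        if not self.sequence:
            raise ValidationError("sequence must be nonempty")


@dataclass
class PredictedStructure:
    """Predictor output: one residue record per input position."""

    residues: list[Residue]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.residues)


class BackendContract(Protocol):
    """Callable surface every predictor backend satisfies.

    Implementations must be deterministic for identical
    (sequence, num_recycles, seed) triples.
    """

    def __call__(self, request: PredictionRequest) -> PredictedStructure: ...


def predict(request: PredictionRequest, backend: BackendContract) -> PredictedStructure:
    """Run one prediction, validate the contract, and stamp provenance."""
    try:
        structure = backend(request)
    except Exception as exc:  # noqa: BLE001 - backend failures become PredictionError
        raise PredictionError(f"backend failed: {exc}", request=request) from exc
    if len(structure.residues) != len(request.sequence):
        raise PredictionError(
            f"backend returned {len(structure.residues)} residues for a "
            f"{len(request.sequence)}-residue sequence",
            request=request,
        )
    structure.provenance.setdefault("seed", request.seed)
    structure.provenance.setdefault("recycles", request.num_recycles)
    return structure


@dataclass
class MockBackend:
    """Deterministic synthetic predictor over the canonical toy geometry.

    The receptor segment is built as an ideal alpha-helix along +z (the linker
    continues the helix and is discarded after excision); the peptide segment
    is an extended strand placed at a controllable minimum heavy-atom distance
    from the receptor.

    Placement distance per call comes from, in order of precedence:

    * ``displacement_by_recycles`` — an explicit recycle-count -> distance
      schedule (callable or mapping) for adaptive-recycling experiments;
    * a seeded random draw: docked with probability ``dock_probability``
      (distance ~ U(4, 7) A, small pose perturbation), otherwise misdocked
      (distance ~ U(10, 30) A, random orientation).

    The random draw is keyed on (sequence bytes, seed, recycles), so masked
    sequence variants genuinely diversify the output while identical requests
    reproduce bit-identical structures — mirroring real predictors, which are
    deterministic per input and insensitive to the seed alone.

    pLDDT modes: ``uniform`` assigns ``uniform_plddt`` everywhere;
    ``contact_correlated`` gives docked peptides high confidence (75-95) and
    misdocked ones low (20-50); ``anticorrelated`` swaps the bands. Receptor
    residues always draw from the high band. Masked positions are treated as
    ordinary residues for geometry but carry low-information pLDDT (20-50).
    """

    spans: dict[str, tuple[int, int]]
    dock_probability: float = 0.4
    displacement_by_recycles: dict[int, float] | Callable[[int], float] | None = None
    noise_sigma: float = 0.0
    plddt_mode: str = "contact_correlated"
    uniform_plddt: float = 70.0
    docked_distance_range: tuple[float, float] = (4.0, 7.0)
    misdocked_distance_range: tuple[float, float] = (10.0, 30.0)
    #: spread (deg, 1 sigma per Euler axis) of docked pose orientations; large
    #: enough that docked placements span incorrect to high quality.
    docked_pose_sigma_deg: float = 35.0

    def _rng(self, request: PredictionRequest) -> np.random.Generator:
        key = zlib.crc32(request.sequence.encode())
        return np.random.default_rng(
            np.random.SeedSequence([key, request.seed & 0x7FFFFFFF, request.num_recycles])
        )

    def _placement_distance(self, request: PredictionRequest,
                            rng: np.random.Generator) -> tuple[float, bool, float]:
        """Placement distance, docked flag, and pose accuracy in [0, 1]
        (0 = near-native orientation)."""
        if self.displacement_by_recycles is not None:
            sched = self.displacement_by_recycles
            d = sched(request.num_recycles) if callable(sched) else sched[request.num_recycles]
            return float(d), d <= DOCK_CUTOFF, 0.0
        if rng.random() < self.dock_probability:
            # One latent accuracy draw couples placement distance and
            # orientation error, giving a continuum of docked pose quality
            # from near-native to barely-touching-and-twisted.
            accuracy = float(rng.random())
            lo_d, hi_d = self.docked_distance_range
            return lo_d + (hi_d - lo_d) * accuracy, True, accuracy
        return float(rng.uniform(*self.misdocked_distance_range)), False, 1.0

    def __call__(self, request: PredictionRequest) -> PredictedStructure:
        seq = request.sequence
        spans = self.spans
        for name in ("receptor", "linker", "peptide"):
            if name not in spans:
                raise ValidationError(f"mock backend spans lack segment {name!r}")
        rng = self._rng(request)

        rec_lo, rec_hi = spans["receptor"]
        pep_lo, pep_hi = spans["peptide"]
        lnk_lo, lnk_hi = spans["linker"]

        # Receptor + linker share one continuous helix; helix index follows
        # position order so the receptor occupies a contiguous turn stack.
        order = sorted([(rec_lo, rec_hi, "receptor"), (lnk_lo, lnk_hi, "linker")])
        helix_len = (rec_hi - rec_lo) + (lnk_hi - lnk_lo)
        helix = geometry.helix_coords(helix_len)
        helix_by_pos: dict[int, dict[str, np.ndarray]] = {}
        h = 0
        for lo, hi, _name in order:
            for pos in range(lo, hi):
                helix_by_pos[pos] = helix[h]
                h += 1

        receptor_res = [helix_by_pos[pos] for pos in range(rec_lo, rec_hi)]
        distance, docked, accuracy = self._placement_distance(request, rng)

        pep_len = pep_hi - pep_lo
        peptide = geometry.extended_coords(pep_len)
        # Centre the strand on the receptor midsection before radial placement.
        rec_atoms = geometry.stack_atoms(receptor_res)
        pep_atoms = geometry.stack_atoms(peptide)
        recentre = rec_atoms.mean(axis=0) - pep_atoms.mean(axis=0)
        recentre[0] += 10.0  # start outside the helix radius, on the +x side
        peptide = geometry.transform_residues(peptide, translation=recentre)

        if docked:
            angles = rng.normal(0.0, 3.0 + self.docked_pose_sigma_deg * accuracy, size=3)
            direction = np.array([1.0, 0.0, 0.0])
        else:
            angles = rng.uniform(-180.0, 180.0, size=3)
            phi = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(phi), np.sin(phi), 0.0])
        pivot = geometry.stack_atoms(peptide).mean(axis=0)
        peptide = geometry.transform_residues(
            peptide, rotation=Rotation.from_euler("xyz", angles, degrees=True), about=pivot
        )
        peptide, _shift = geometry.place_at_min_distance(
            peptide, receptor_res, target=distance, direction=direction
        )
        if self.noise_sigma > 0:
            peptide = [
                {n: xyz + rng.normal(0.0, self.noise_sigma, 3) for n, xyz in res.items()}
                for res in peptide
            ]

        plddt = self._plddt_profile(seq, spans, docked, rng)
        residues = []
        pep_cursor = 0
        for pos, aa in enumerate(seq):
            if rec_lo <= pos < rec_hi or lnk_lo <= pos < lnk_hi:
                atoms = helix_by_pos[pos]
            else:
                atoms = peptide[pep_cursor]
                pep_cursor += 1
            residues.append(Residue(pos, aa, dict(atoms), plddt[pos]))
        return PredictedStructure(
            residues=residues,
            provenance={
                "backend": "mock",
                "seed": request.seed,
                "recycles": request.num_recycles,
                "placement_distance": distance,
                "docked": docked,
            },
        )

    def _plddt_profile(self, seq, spans, docked, rng) -> np.ndarray:
        n = len(seq)
        high = rng.uniform(75.0, 95.0, size=n)
        low = rng.uniform(20.0, 50.0, size=n)
        if self.plddt_mode == "uniform":
            values = np.full(n, float(self.uniform_plddt))
        elif self.plddt_mode in ("contact_correlated", "anticorrelated"):
            peptide_high = docked if self.plddt_mode == "contact_correlated" else not docked
            values = high.copy()
            lo, hi = spans["peptide"]
            if not peptide_high:
                values[lo:hi] = low[lo:hi]
        else:
            raise ValidationError(f"unknown pLDDT mode {self.plddt_mode!r}")
        masked = np.array([ch == MASK_SYMBOL for ch in seq])
        values[masked] = np.minimum(values[masked], low[masked])
        return values


def adaptive_predict(
    request: PredictionRequest,
    backend: BackendContract,
    spans: dict[str, tuple[int, int]],
    base: int = DEFAULT_RECYCLES,
    maximum: int = MAX_RECYCLES,
    step: int = RECYCLE_STEP,
    dock_cutoff: float = DOCK_CUTOFF,
) -> tuple[PredictedStructure, int, bool]:
    """Predict with escalating recycles until the peptide docks.

    Runs at ``base`` recycles; while the peptide's minimum heavy-atom distance
    to the receptor exceeds ``dock_cutoff`` and recycles < ``maximum``, reruns
    with the recycle count raised by ``step``. Returns the first docked
    structure, or the ``maximum``-recycle structure with ``docked=False``.
    """
    if maximum < base:
        raise ConfigurationError(f"maximum recycles {maximum} < base {base}")
    if step <= 0:
        raise ConfigurationError("recycle step must be positive")

    recycles = base
    while True:
        structure = predict(
            PredictionRequest(request.sequence, recycles, request.seed), backend
        )
        model = split_and_excise(structure, spans)
        if min_interchain_distance(model) <= dock_cutoff:
            return structure, recycles, True
        if recycles >= maximum:
            return structure, recycles, False
        recycles = min(recycles + step, maximum)
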