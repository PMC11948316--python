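"""Sequence preparation for single-chain docking.

A single-chain structure predictor models one polypeptide at a time. To dock a
peptide onto a receptor we fuse the two sequences with a flexible polyglycine
linker, predict the fusion as a single chain, and excise the linker afterwards.
Sampling diversity is obtained by masking a fixed fraction of residues in the
fused sequence before each prediction: the predictor sees partially hidden
input and produces alternative placements.

This module owns the fusion bookkeeping (where each segment sits in the fused
text) and the deterministic generation of masked sequence variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Reserved placeholder for masked positions. Distinct from every standard
#: one-letter code, so polyglycine linkers can never collide with it.
MASK_SYMBOL = "X"

PEPTIDE_AT_C_TERMINUS = "peptide_at_C_terminus"
PEPTIDE_AT_N_TERMINUS = "peptide_at_N_terminus"

ELIGIBLE_RECEPTOR_AND_PEPTIDE = "receptor_and_peptide"
ELIGIBLE_WHOLE_FUSION = "whole_fusion"


def _validate_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValidationError(f"{label} sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in STANDARD_AA:
            raise ValidationError(
                f"non-standard residue {ch!r} at position {i} of {label} sequence"
            )


@dataclass(frozen=True)
class ChainPair:
    """A receptor sequence and the peptide to be docked onto it."""

    receptor_id: str
    receptor_seq: str
    peptide_id: str
    peptide_seq: str

    def __post_init__(self) -> None:
        _validate_sequence(self.receptor_seq, "receptor")
        _validate_sequence(self.peptide_seq, "peptide")


@dataclass(frozen=True)
class LinkerSpec:
    """Polyglycine linker between receptor and peptide.

    A 30-residue glycine linker with the peptide at the C-terminus is the
    default; longer linkers (100, 200) and N-terminal placement are supported
    but do not improve docking in practice.
    """

    length: int = 30
    placement: str = PEPTIDE_AT_C_TERMINUS
    symbol: str = "G"

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValidationError("linker length must be >= 0")
        if self.symbol not in STANDARD_AA:
            raise ValidationError(f"linker symbol {self.symbol!r} is not a standard residue")
        if self.placement not in (PEPTIDE_AT_C_TERMINUS, PEPTIDE_AT_N_TERMINUS):
            raise ValidationError(f"unknown linker placement {self.placement!r}")


@dataclass(frozen=True)
class FusedSequence:
    """Fused receptor-linker-peptide text with 0-based half-open segment spans."""

    sequence: str
    receptor_span: tuple[int, int]
    linker_span: tuple[int, int]
    peptide_span: tuple[int, int]

    def __post_init__(self) -> None:
        spans = sorted([self.receptor_span, self.linker_span, self.peptide_span])
        if spans[0][0] != 0 or spans[-1][1] != len(self.sequence):
            raise ValidationError("segment spans do not cover the fused sequence")
        for (a, b), (c, _) in zip(spans, spans[1:]):
            if b != c:
                raise ValidationError("segment spans overlap or leave gaps")

    @property
    def receptor_seq(self) -> str:
        return self.sequence[slice(*self.receptor_span)]

    @property
    def linker_seq(self) -> str:
        return self.sequence[slice(*self.linker_span)]

    @property
    def peptide_seq(self) -> str:
        return self.sequence[slice(*self.peptide_span)]

    def spans(self) -> dict[str, tuple[int, int]]:
        return {
            "receptor": self.receptor_span,
            "linker": self.linker_span,
            "peptide": self.peptide_span,
        }


@dataclass(frozen=True)
class MaskSpec:
    """Random-masking parameters for sampling diversity.

    ``rate`` is the fixed fraction of eligible positions replaced by the mask
    placeholder in each variant (count = round(rate * n_eligible), sampled
    without replacement). The linker is scaffold and is excluded from masking
    under the default eligibility policy.
    """

    rate: float = 0.25
    n_variants: int = 8
    mask_symbol: str = MASK_SYMBOL
    eligible_policy: str = ELIGIBLE_RECEPTOR_AND_PEPTIDE

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValidationError(f"masking rate {self.rate} outside [0, 1]")
        if self.n_variants < 1:
            raise ValidationError("n_variants must be >= 1")
        if self.eligible_policy not in (
            ELIGIBLE_RECEPTOR_AND_PEPTIDE,
            ELIGIBLE_WHOLE_FUSION,
        ):
            raise ValidationError(f"unknown eligibility policy {self.eligible_policy!r}")


def fuse(pair: ChainPair, linker: LinkerSpec = LinkerSpec()) -> FusedSequence:
    """Concatenate receptor and peptide around a polyglycine linker.

    With the default placement the fused text is receptor + linker + peptide;
    the alternative placement mirrors it (peptide + linker + receptor).
    """
    r, p, L = pair.receptor_seq, pair.peptide_seq, linker.length
    link = linker.symbol * L
    if linker.placement == PEPTIDE_AT_C_TERMINUS:
        seq = r + link + p
        receptor_span = (0, len(r))
        linker_span = (len(r), len(r) + L)
        peptide_span = (len(r) + L, len(seq))
    else:
        seq = p + link + r
        peptide_span = (0, len(p))
        linker_span = (len(p), len(p) + L)
        receptor_span = (len(p) + L, len(seq))
    return FusedSequence(seq, receptor_span, linker_span, peptide_span)


def eligible_positions(fused: FusedSequence, spec: MaskSpec) -> np.ndarray:
    """Positions that masking may touch under the spec's eligibility policy."""
    if spec.eligible_policy == ELIGIBLE_WHOLE_FUSION:
        return np.arange(len(fused.sequence))
    rec = np.arange(*fused.receptor_span)
    pep = np.arange(*fused.peptide_span)
    return np.sort(np.concatenate([rec, pep]))


def mask_variants(fused: FusedSequence, spec: MaskSpec, seed: int) -> list[str]:
    """Generate ``spec.n_variants`` masked copies of the fused sequence.

    Each variant masks exactly ``round(rate * n_eligible)`` eligible positions,
    sampled without replacement with a per-variant RNG seeded ``seed + index``,
    so identical inputs always yield byte-identical variant lists.
    """
    eligible = eligible_positions(fused, spec)
    n_mask = int(round(spec.rate * len(eligible)))
    if spec.rate > 0 and len(eligible) == 0:
        raise ValidationError("no eligible positions to mask at a nonzero rate")
    variants = []
    for k in range(spec.n_variants):
        rng = np.random.default_rng(seed + k)
        chosen = rng.choice(eligible, size=n_mask, replace=False) if n_mask else []
        chars = list(fused.sequence)
        for pos in chosen:
            chars[pos] = spec.mask_symbol
        variants.append("".join(chars))
    return variants


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_chain_pair(*paths) -> ChainPair:
    """Read a receptor/peptide pair from FASTA.

    Accepts either a single file with two records (receptor first, peptide
    second) or two files (receptor file, peptide file).
    """
    records: list[SeqRecord] = []
    for path in paths:
        records.extend(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValidationError(
            f"expected exactly 2 FASTA records (receptor, peptide); got {len(records)}"
        )
    rec, pep = records
    return ChainPair(rec.id, str(rec.seq).upper(), pep.id, str(pep.seq).upper())


def _span_map_description(fused: FusedSequence) -> str:
    return ";".join(
        f"{name}={a}-{b}" for name, (a, b) in fused.spans().items()
    )


def write_fused(fused: FusedSequence, path, record_id: str = "fusion",
                sequence: str | None = None) -> None:
    """Write a fused (optionally masked) sequence as FASTA.

    The segment map is encoded in the record description as 0-based half-open
    intervals, e.g. ``receptor=0-5;linker=5-8;peptide=8-11``.
    """
    seq = fused.sequence if sequence is None else sequence
    if len(seq) != len(fused.sequence):
        raise ValidationError("sequence length does not match the segment map")
    record = SeqRecord(Seq(seq), id=record_id, description=_span_map_description(fused))
    SeqIO.write([record], str(path), "fasta")


def read_fused(path) -> FusedSequence:
    """Read a fused sequence written by :func:`write_fused`."""
    record = next(SeqIO.parse(str(path), "fasta"))
    spans: dict[str, tuple[int, int]] = {}
    for part in record.description.split()[-1].split(";"):
        name, _, interval = part.partition("=")
        a, _, b = interval.partition("-")
        spans[name] = (int(a), int(b))
    missing = {"receptor", "linker", "peptide"} - spans.keys()
    if missing:
        raise ValidationError(f"FASTA description lacks segment spans for: {sorted(missing)}")
    return FusedSequence(
        str(record.seq), spans["receptor"], spans["linker"], spans["peptide"]
    )
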