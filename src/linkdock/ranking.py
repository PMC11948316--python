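"""pLDDT-based scoring, ranking and filtering of candidate docking models.

When several models are produced per complex (one per masked variant), the one
to report is chosen by predictor confidence. Three schemes are supported, all
built from the peptide's per-residue pLDDT:

``mean_peptide``
    the plain mean over all peptide residues;
``interface_only``
    the mean over peptide residues within ``contact_cutoff`` (default 5 A) of
    the receptor, 0 when nothing is in contact;
``contact_weighted``
    the sum of pLDDT over contacting peptide residues divided by the total
    peptide length — equivalently the interface mean weighted by the fraction
    of residues in contact, with noncontacting residues contributing zero.
    This is the most discriminative scheme in practice: a confidently placed
    but detached peptide scores zero.

Models whose peptide sits more than 8 A from the receptor are clearly
misdocked and are discarded before any success-rate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .structure import (
    DOCK_CUTOFF,
    ComplexModel,
    contacting_peptide_residues,
    is_docked,
)

INTERFACE_CUTOFF = 5.0

MEAN_PEPTIDE = "mean_peptide"
INTERFACE_ONLY = "interface_only"
CONTACT_WEIGHTED = "contact_weighted"

MAXIMIZE = "maximize"
MINIMIZE = "minimize"


@dataclass(frozen=True)
class RankingScheme:
    """A named pLDDT scoring rule plus the direction in which it is ranked.

    ``direction`` defaults to maximize for every scheme; minimize is exposed
    for protocols that deliberately chase low-confidence (hence diverse)
    placements.
    """

    name: str = CONTACT_WEIGHTED
    contact_cutoff: float = INTERFACE_CUTOFF
    direction: str = MAXIMIZE

    def __post_init__(self) -> None:
        if self.name not in (MEAN_PEPTIDE, INTERFACE_ONLY, CONTACT_WEIGHTED):
            raise ValidationError(f"unknown ranking scheme {self.name!r}")
        if self.contact_cutoff <= 0:
            raise ValidationError("contact cutoff must be positive")
        if self.direction not in (MAXIMIZE, MINIMIZE):
            raise ValidationError(f"unknown ranking direction {self.direction!r}")


@dataclass
class ScoredModel:
    """A candidate model with its scheme scores and selection state."""

    model: ComplexModel
    variant_index: int
    scheme_scores: dict[str, float]
    docked: bool
    selected: bool = False


def mean_peptide_plddt(model: ComplexModel) -> float:
    """Arithmetic mean pLDDT over all peptide residues."""
    if not model.peptide:
        raise ValidationError("peptide chain is empty")
    return float(np.mean([r.plddt for r in model.peptide]))


def interface_plddt(model: ComplexModel, cutoff: float = INTERFACE_CUTOFF) -> float:
    """Mean pLDDT over peptide residues in contact with the receptor.

    Returns 0 when no peptide residue lies within ``cutoff`` of the receptor,
    so detached peptides sort last under a maximizing scheme.
    """
    contacts = contacting_peptide_residues(model, cutoff)
    if not contacts:
        return 0.0
    return float(np.mean([r.plddt for r in model.peptide if r.number in contacts]))


def contact_weighted_plddt(model: ComplexModel, cutoff: float = INTERFACE_CUTOFF) -> float:
    """Interface pLDDT weighted by the fraction of peptide residues in contact.

    Noncontacting residues contribute zero, i.e. the score is
    sum(pLDDT of contacting residues) / len(peptide).
    """
    contacts = contacting_peptide_residues(model, cutoff)
    total = sum(r.plddt for r in model.peptide if r.number in contacts)
    return float(total / len(model.peptide))


_SCHEME_FUNCS = {
    MEAN_PEPTIDE: lambda m, cutoff: mean_peptide_plddt(m),
    INTERFACE_ONLY: interface_plddt,
    CONTACT_WEIGHTED: contact_weighted_plddt,
}


def score_model(model: ComplexModel, scheme: RankingScheme) -> float:
    return _SCHEME_FUNCS[scheme.name](model, scheme.contact_cutoff)


def rank_and_select(models: list[ComplexModel],
                    scheme: RankingScheme = RankingScheme()) -> list[ScoredModel]:
    """Order candidate models by a scoring scheme and mark the top one selected.

    Ties are broken by higher mean peptide pLDDT, then by lower variant index
    (input order). The returned list is a permutation of the input with all
    three scheme scores attached.
    """
    if not models:
        raise ValidationError("cannot rank an empty model collection")
    scored = []
    for idx, model in enumerate(models):
        scores = {
            MEAN_PEPTIDE: mean_peptide_plddt(model),
            INTERFACE_ONLY: interface_plddt(model, scheme.contact_cutoff),
            CONTACT_WEIGHTED: contact_weighted_plddt(model, scheme.contact_cutoff),
        }
        scored.append(
            ScoredModel(model, idx, scores, docked=is_docked(model))
        )
    sign = -1.0 if scheme.direction == MAXIMIZE else 1.0
    scored.sort(
        key=lambda s: (
            sign * s.scheme_scores[scheme.name],
            -s.scheme_scores[MEAN_PEPTIDE],
            s.variant_index,
        )
    )
    scored[0].selected = True
    return scored


def filter_misdocked(scored: list[ScoredModel], cutoff: float = DOCK_CUTOFF) -> list[ScoredModel]:
    """Keep only models whose peptide touches the receptor at the cutoff."""
    return [s for s in scored if is_docked(s.model, cutoff)]


def is_high_confidence(model: ComplexModel) -> bool:
    """True when the mean pLDDT over both chains strictly exceeds 70."""
    return model.mean_plddt() > 70.0


def ranking_report(scored: list[ScoredModel]) -> pd.DataFrame:
    """Tab-separable report: one row per model with scores and flags."""
    return pd.DataFrame(
        [
            {
                "variant": s.variant_index,
                MEAN_PEPTIDE: s.scheme_scores[MEAN_PEPTIDE],
                INTERFACE_ONLY: s.scheme_scores[INTERFACE_ONLY],
                CONTACT_WEIGHTED: s.scheme_scores[CONTACT_WEIGHTED],
                "docked": s.docked,
                "selected": s.selected,
            }
            for s in scored
        ]
    )
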