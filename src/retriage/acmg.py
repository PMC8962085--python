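"""ACMG/AMP criterion assignment and five-tier combining.

``evaluate_criteria`` maps structured evidence facts for one variant to
criterion assignments at modulated strengths (PM2 is applied at supporting
strength by default, following current ClinGen SVI practice).
``combine_criteria`` implements the guideline combining table over applied
strengths: apart from the stand-alone BA1 shortcut it never inspects the
criterion code, only its direction and strength, so strength-modulated
evidence combines exactly like natively weighted evidence.

The PVS1 decision tree is deliberately reduced to a three-way switch on the
NMD prediction (unknown counts as very strong); the full loss-of-function
decision tree is a documented extension point.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .config import EvidenceConflictError, RunConfig
from .knowledge_base import AssertedClass, GeneDiseaseEntry, VariantAssertion
from .variant_model import AlleleOrigin, ConsequenceCategory, Variant


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Direction(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Tier(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"

    @classmethod
    def from_asserted(cls, asserted: AssertedClass) -> "Tier":
        return cls(asserted.value)


#: Order used by the monotonicity property: benign end first.
TIER_ORDER = (Tier.B, Tier.LB, Tier.VUS, Tier.LP, Tier.P)

_PATHOGENIC_PREFIXES = ("PVS", "PS", "PM", "PP")
_BENIGN_PREFIXES = ("BA", "BS", "BP")


def criterion_direction(code: str) -> Direction:
    if any(code.startswith(p) for p in _PATHOGENIC_PREFIXES):
        return Direction.PATHOGENIC
    if any(code.startswith(p) for p in _BENIGN_PREFIXES):
        return Direction.BENIGN
    raise ValueError(f"unknown criterion code {code!r}")


@dataclass(frozen=True)
class CriterionAssignment:
    code: str
    applied_strength: Strength
    rationale: str = ""

    def __post_init__(self) -> None:
        _ = criterion_direction(self.code)  # validates the code family
        if self.code == "BA1" and self.applied_strength is not Strength.STAND_ALONE:
            raise ValueError("BA1 is stand-alone only")
        if self.applied_strength is Strength.STAND_ALONE and self.code != "BA1":
            raise ValueError("only BA1 may be stand-alone")

    @property
    def direction(self) -> Direction:
        return criterion_direction(self.code)


@dataclass
class VariantClassification:
    """A five-tier class together with the assignments that produced it.

    ``assignments`` may be empty for externally asserted classes (e.g. a
    transcribed report table); the audit round-trip only applies when the
    evidence trail is present.
    """

    tier: Tier
    assignments: tuple[CriterionAssignment, ...] = ()
    classified_on: dt.date | None = None

    def recomputed_tier(self) -> Tier:
        return combine_criteria(self.assignments)


@dataclass
class EvidenceFacts:
    """Structured inputs an annotation stack supplies for one variant."""

    population_af: float | None = None
    #: True when population databases were consulted and the variant was not
    #: seen (informative absence); a None ``population_af`` alone means the
    #: frequency is simply unknown and PM2 does not apply.
    population_absent: bool = False
    lof_mechanism: bool = False
    nmd_predicted: bool | None = None
    matching_assertion: VariantAssertion | None = None
    same_residue_assertion: VariantAssertion | None = None
    de_novo: bool = False
    in_trans_with_plp: bool = False
    insilico_consensus: str = "none"  # pathogenic_support | benign_support | none
    segregation_observed: bool = False

    def __post_init__(self) -> None:
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError(f"population_af {self.population_af} outside [0, 1]")
        if self.insilico_consensus not in ("pathogenic_support", "benign_support", "none"):
            raise ValueError(f"bad insilico_consensus {self.insilico_consensus!r}")


def evaluate_criteria(
    variant: Variant,
    facts: EvidenceFacts,
    entry: GeneDiseaseEntry,
    config: RunConfig | None = None,
) -> list[CriterionAssignment]:
    """Deterministic evidence-to-criteria mapping for one variant.

    Raises :class:`EvidenceConflictError` when the de novo flag contradicts
    a recorded parental inheritance.
    """
    config = config or RunConfig()
    if facts.de_novo and variant.allele_origin in (
        AlleleOrigin.INHERITED_AFFECTED_PARENT,
        AlleleOrigin.INHERITED_UNAFFECTED_PARENT,
    ):
        raise EvidenceConflictError(
            f"{variant.key}: de novo flag conflicts with origin "
            f"{variant.allele_origin.value}"
        )

    af = facts.population_af
    if af is not None and af > config.ba1_af:
        return [
            CriterionAssignment(
                "BA1",
                Strength.STAND_ALONE,
                f"allele frequency {af:g} exceeds {config.ba1_af:g}",
            )
        ]

    out: list[CriterionAssignment] = []
    consequence = variant.consequence

    if facts.lof_mechanism and consequence in (
        ConsequenceCategory.FRAMESHIFT,
        ConsequenceCategory.STOP_GAIN,
        ConsequenceCategory.CANONICAL_SPLICE,
    ):
        if facts.nmd_predicted is False:
            strength, note = Strength.MODERATE, "NMD escape predicted"
        else:
            strength, note = Strength.VERY_STRONG, "NMD predicted or unknown"
        out.append(
            CriterionAssignment(
                "PVS1",
                strength,
                f"{consequence.value} in a gene with loss-of-function mechanism; {note}",
            )
        )

    if (
        facts.matching_assertion is not None
        and facts.matching_assertion.asserted_class is AssertedClass.P
    ):
        out.append(
            CriterionAssignment(
                "PS1",
                Strength.STRONG,
                "same protein change previously asserted pathogenic "
                f"({facts.matching_assertion.source or 'curated source'})",
            )
        )
    if facts.same_residue_assertion is not None:
        out.append(
            CriterionAssignment(
                "PM5",
                Strength.MODERATE,
                "different pathogenic change at the same residue "
                f"({facts.same_residue_assertion.variant_key})",
            )
        )

    if facts.de_novo:
        out.append(
            CriterionAssignment(
                "PS2", Strength.STRONG, "assumed de novo (parents negative by Sanger)"
            )
        )

    pm2_cutoff = (
        config.pm2_af_recessive
        if entry.inheritance.recessive_like and not entry.inheritance.dominant_like
        else config.pm2_af_dominant
    )
    if (af is None and facts.population_absent) or (af is not None and af < pm2_cutoff):
        out.append(
            CriterionAssignment(
                "PM2",
                Strength(config.pm2_strength),
                "absent from population databases"
                if af is None
                else f"allele frequency {af:g} below {pm2_cutoff:g}",
            )
        )

    if facts.in_trans_with_plp and entry.inheritance.recessive_like:
        out.append(
            CriterionAssignment(
                "PM3",
                Strength.MODERATE,
                "in trans with a pathogenic/likely pathogenic allele in a "
                "recessive gene",
            )
        )

    if consequence is ConsequenceCategory.INFRAME_INDEL:
        out.append(
            CriterionAssignment(
                "PM4", Strength.MODERATE, "protein length change (in-frame indel)"
            )
        )

    if facts.segregation_observed:
        out.append(
            CriterionAssignment(
                "PP1", Strength.SUPPORTING, "co-segregation with disease observed"
            )
        )

    if facts.insilico_consensus == "pathogenic_support":
        out.append(
            CriterionAssignment(
                "PP3", Strength.SUPPORTING, "in silico consensus deleterious"
            )
        )
    elif facts.insilico_consensus == "benign_support":
        out.append(
            CriterionAssignment(
                "BP4", Strength.SUPPORTING, "in silico consensus benign"
            )
        )

    bs1_cutoff = config.bs1_af.get(entry.disease_id)
    if af is not None and bs1_cutoff is not None and af > bs1_cutoff:
        out.append(
            CriterionAssignment(
                "BS1",
                Strength.STRONG,
                f"allele frequency {af:g} above disease maximum credible "
                f"frequency {bs1_cutoff:g}",
            )
        )
    return out


def _strength_counts(
    assignments: Iterable[CriterionAssignment], direction: Direction
) -> dict[Strength, int]:
    counts = {s: 0 for s in Strength}
    for a in assignments:
        if a.direction is direction:
            counts[a.applied_strength] += 1
    return counts


def combine_criteria(assignments: Sequence[CriterionAssignment]) -> Tier:
    """Combine applied-strength criteria into one of the five tiers.

    Simultaneous qualification as pathogenic(-likely) and benign(-likely),
    or qualification as neither, yields VUS.
    """
    path = _strength_counts(assignments, Direction.PATHOGENIC)
    ben = _strength_counts(assignments, Direction.BENIGN)
    vs, s, m, p = (
        path[Strength.VERY_STRONG],
        path[Strength.STRONG],
        path[Strength.MODERATE],
        path[Strength.SUPPORTING],
    )
    bsa, bs, bp = (
        ben[Strength.STAND_ALONE],
        ben[Strength.STRONG],
        ben[Strength.SUPPORTING] + ben[Strength.MODERATE],
    )

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = bsa >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_q = pathogenic or likely_pathogenic
    ben_q = benign or likely_benign
    if path_q and ben_q:
        return Tier.VUS
    if pathogenic:
        return Tier.P
    if likely_pathogenic:
        return Tier.LP
    if benign:
        return Tier.B
    if likely_benign:
        return Tier.LB
    return Tier.VUS


def count_moderate_pathogenic(assignments: Iterable[CriterionAssignment]) -> int:
    """Number of pathogenic-direction criteria applied at moderate strength."""
    return sum(
        1
        for a in assignments
        if a.direction is Direction.PATHOGENIC
        and a.applied_strength is Strength.MODERATE
    )


def classify(
    variant: Variant,
    facts: EvidenceFacts,
    entry: GeneDiseaseEntry,
    config: RunConfig | None = None,
    classified_on: dt.date | None = None,
) -> VariantClassification:
    """Evaluate and combine in one step."""
    assignments = tuple(evaluate_criteria(variant, facts, entry, config))
    return VariantClassification(
        tier=combine_criteria(assignments),
        assignments=assignments,
        classified_on=classified_on,
    )
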