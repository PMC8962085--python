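"""Report triage: positive / inconclusive / negative per patient.

The category is decided per implicated gene-disease entry:

POSITIVE
    One het/hemi P/LP variant in a fitting, OMIM-registered dominant or
    X-linked entry (digenic entries are handled the same way); or, in a
    fitting registered recessive entry, a homozygous P/LP variant, two P/LP
    potential compound heterozygotes, or a P/LP plus a VUS carrying at
    least two moderate pathogenic criteria.

INCONCLUSIVE
    A VUS in a fitting registered entry (single dominant/X-linked VUS, a
    recessive P/LP + VUS with at most one moderate criterion, or multiple
    VUS); any P/LP in a literature-candidate entry; or a P/LP in a
    registered entry whose phenotype fit is below threshold (pending
    additional phenotyping).

NEGATIVE
    Otherwise.

Phenotype fit is the similarity score >= threshold (default 5) against the
entry's HPO profile; ``assume_phenotype_fit`` treats fit as satisfied when
patient HPO terms are not available (e.g. transcribed report tables).
Entries with both dominant and recessive inheritance are tested under both
rule sets and the more conclusive category wins.  All qualifying entries
are reported, so dual diagnoses are supported.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .acmg import Tier, VariantClassification, count_moderate_pathogenic
from .config import EmptyPhenotypeError, RunConfig
from .knowledge_base import GeneDiseaseEntry, Registration, Snapshot
from .phenotype import Ontology, similarity_score
from .variant_model import (
    Variant,
    Zygosity,
    group_by_gene,
    normalize_gene,
    potential_comp_het,
)

logger = logging.getLogger(__name__)


class ReportCategory(str, Enum):
    POSITIVE = "positive"
    INCONCLUSIVE = "inconclusive"
    NEGATIVE = "negative"


class VariantRole(str, Enum):
    PRIMARY = "primary"
    COMP_HET_PARTNER = "comp_het_partner"
    SECONDARY_FINDING = "secondary_finding"


@dataclass
class ClassifiedVariant:
    """A patient variant together with its current classification."""

    variant: Variant
    classification: VariantClassification | None = None

    @property
    def tier(self) -> Tier | None:
        return self.classification.tier if self.classification else None

    @property
    def is_plp(self) -> bool:
        return self.tier in (Tier.P, Tier.LP)

    @property
    def moderate_pathogenic_count(self) -> int:
        if self.classification is None:
            return 0
        return count_moderate_pathogenic(self.classification.assignments)


@dataclass
class PatientCase:
    patient_id: str
    hpo_terms: frozenset[str] = frozenset()
    variants: list[ClassifiedVariant] = field(default_factory=list)
    family_id: str | None = None
    enrollment_date: dt.date | None = None
    report_history: list["Report"] = field(default_factory=list)
    #: per-variant-key overrides merged into the evidence facts built from a
    #: snapshot (in silico consensus, NMD prediction, segregation, ...)
    evidence_notes: dict[str, dict] = field(default_factory=dict)

    @property
    def latest_report(self) -> "Report | None":
        return self.report_history[-1] if self.report_history else None

    def variant_by_key(self, key: str) -> ClassifiedVariant | None:
        for cv in self.variants:
            if cv.variant.key == key:
                return cv
        return None


@dataclass(frozen=True)
class ReportedVariant:
    variant_key: str
    role: VariantRole
    tier: Tier
    disease_id: str


@dataclass
class Report:
    patient_id: str
    category: ReportCategory
    reported_variants: list[ReportedVariant] = field(default_factory=list)
    rule_citations: list[str] = field(default_factory=list)
    similarity_scores: dict[str, float | None] = field(default_factory=dict)
    report_date: dt.date | None = None

    def variants_with_role(self, *roles: VariantRole) -> list[ReportedVariant]:
        return [rv for rv in self.reported_variants if rv.role in roles]


@dataclass
class _EntryFinding:
    """Outcome of applying the reporting rules to one gene-disease entry."""

    category: ReportCategory
    reported: list[ReportedVariant]
    citation: str


def _phenotype_fit(
    case: PatientCase,
    entry: GeneDiseaseEntry,
    ontology: Ontology | None,
    config: RunConfig,
) -> tuple[bool, float | None]:
    if config.assume_phenotype_fit or ontology is None:
        return True, None
    try:
        result = similarity_score(case.hpo_terms, entry.hpo_profile, ontology)
    except EmptyPhenotypeError:
        return False, None
    return result.score >= config.similarity_threshold, result.score


def _evaluate_entry(
    entry: GeneDiseaseEntry,
    gene_variants: Sequence[ClassifiedVariant],
    fit: bool,
    config: RunConfig,
) -> _EntryFinding | None:
    registered = entry.registration is Registration.OMIM_REGISTERED
    did = entry.disease_id
    plp = [cv for cv in gene_variants if cv.is_plp]
    vus = [cv for cv in gene_variants if cv.tier is Tier.VUS]

    def rep(cv: ClassifiedVariant, role: VariantRole) -> ReportedVariant:
        return ReportedVariant(cv.variant.key, role, cv.tier, did)  # type: ignore[arg-type]

    # --- positive arms (registered entry, phenotype fit) ------------------
    if registered and fit:
        if entry.inheritance.dominant_like or entry.digenic:
            mono = [
                cv
                for cv in plp
                if cv.variant.zygosity
                in (Zygosity.HETEROZYGOUS, Zygosity.HEMIZYGOUS, Zygosity.HOMOZYGOUS)
            ]
            if mono:
                mode = "digenic" if entry.digenic else entry.inheritance.value
                return _EntryFinding(
                    ReportCategory.POSITIVE,
                    [rep(cv, VariantRole.PRIMARY) for cv in mono],
                    f"het/hemi P/LP variant in registered {mode} entry {did}",
                )
        if entry.inheritance.recessive_like:
            finding = _recessive_positive(entry, gene_variants, rep)
            if finding is not None:
                return finding

    # --- inconclusive arms -------------------------------------------------
    if plp and not registered:
        return _EntryFinding(
            ReportCategory.INCONCLUSIVE,
            [rep(cv, VariantRole.PRIMARY) for cv in plp],
            f"P/LP variant in literature-candidate entry {did} "
            "(not yet an OMIM disease)",
        )
    if plp and registered and not fit:
        return _EntryFinding(
            ReportCategory.INCONCLUSIVE,
            [rep(cv, VariantRole.PRIMARY) for cv in plp],
            f"P/LP variant in registered entry {did}; additional phenotyping "
            "needed to confirm the phenotypic match",
        )
    if vus and registered and fit:
        reported = [rep(cv, VariantRole.PRIMARY) for cv in vus]
        # a recessive P/LP partner with a weak VUS stays inconclusive but is
        # cited alongside it
        if plp and entry.inheritance.recessive_like:
            reported += [rep(cv, VariantRole.COMP_HET_PARTNER) for cv in plp]
            citation = (
                f"potential compound heterozygote in registered AR entry {did}: "
                "P/LP with a VUS carrying at most one moderate pathogenic criterion"
            )
        else:
            citation = f"VUS in fitting registered entry {did}"
        return _EntryFinding(ReportCategory.INCONCLUSIVE, reported, citation)
    return None


def _recessive_positive(
    entry: GeneDiseaseEntry,
    gene_variants: Sequence[ClassifiedVariant],
    rep,
) -> _EntryFinding | None:
    did = entry.disease_id
    by_variant = {id(cv.variant): cv for cv in gene_variants}
    pairs = potential_comp_het([cv.variant for cv in gene_variants], entry.inheritance)
    hom_plp = [
        cv
        for cv in gene_variants
        if cv.variant.zygosity is Zygosity.HOMOZYGOUS and cv.is_plp
    ]
    if hom_plp:
        return _EntryFinding(
            ReportCategory.POSITIVE,
            [rep(cv, VariantRole.PRIMARY) for cv in hom_plp],
            f"homozygous P/LP variant in registered AR entry {did}",
        )
    for pair in pairs:
        if pair.is_homozygous:
            continue
        a = by_variant[id(pair.first)]
        b = by_variant[id(pair.second)]
        if a.is_plp and b.is_plp:
            return _EntryFinding(
                ReportCategory.POSITIVE,
                [rep(a, VariantRole.PRIMARY), rep(b, VariantRole.COMP_HET_PARTNER)],
                f"two P/LP potential compound heterozygous variants in "
                f"registered AR entry {did}",
            )
    for pair in pairs:
        if pair.is_homozygous:
            continue
        a = by_variant[id(pair.first)]
        b = by_variant[id(pair.second)]
        for plp_cv, vus_cv in ((a, b), (b, a)):
            if (
                plp_cv.is_plp
                and vus_cv.tier is Tier.VUS
                and vus_cv.moderate_pathogenic_count >= 2
            ):
                return _EntryFinding(
                    ReportCategory.POSITIVE,
                    [
                        rep(plp_cv, VariantRole.PRIMARY),
                        rep(vus_cv, VariantRole.COMP_HET_PARTNER),
                    ],
                    f"potential compound heterozygote in registered AR entry {did}: "
                    "P/LP with a VUS carrying 2 moderate pathogenic criteria",
                )
    return None


_CATEGORY_RANK = {
    ReportCategory.POSITIVE: 2,
    ReportCategory.INCONCLUSIVE: 1,
    ReportCategory.NEGATIVE: 0,
}


def triage_case(
    case: PatientCase,
    snapshot: Snapshot,
    ontology: Ontology | None = None,
    config: RunConfig | None = None,
    report_date: dt.date | None = None,
) -> Report:
    """Apply the reporting rules to one classified case."""
    config = config or RunConfig()
    report = Report(
        patient_id=case.patient_id,
        category=ReportCategory.NEGATIVE,
        report_date=report_date or snapshot.snapshot_date,
    )
    findings: list[_EntryFinding] = []
    for gene, variants in sorted(
        group_by_gene([cv.variant for cv in case.variants]).items()
    ):
        cvs = [cv for cv in case.variants if normalize_gene(cv.variant.gene_symbol) == gene]
        entries = snapshot.entries_for_gene(gene)
        if not entries:
            if any(cv.is_plp or cv.tier is Tier.VUS for cv in cvs):
                logger.warning(
                    "patient %s: gene %s absent from knowledge base; "
                    "variants ignored for triage",
                    case.patient_id,
                    gene,
                )
            continue
        for entry in sorted(entries, key=lambda e: e.disease_id):
            fit, score = _phenotype_fit(case, entry, ontology, config)
            report.similarity_scores[entry.disease_id] = score
            finding = _evaluate_entry(entry, cvs, fit, config)
            if finding is not None:
                findings.append(finding)

    if findings:
        best = max(_CATEGORY_RANK[f.category] for f in findings)
        report.category = ReportCategory(
            [c for c, r in _CATEGORY_RANK.items() if r == best][0]
        )
        seen: set[tuple[str, str]] = set()
        for f in findings:
            if _CATEGORY_RANK[f.category] != best:
                continue
            report.rule_citations.append(f.citation)
            for rv in f.reported:
                if (rv.variant_key, rv.disease_id) not in seen:
                    seen.add((rv.variant_key, rv.disease_id))
                    report.reported_variants.append(rv)
    return report


@dataclass
class CohortSummary:
    n_cases: int = 0
    by_category: dict[str, int] = field(default_factory=dict)
    reported_variants_in_positive: int = 0
    vus_in_non_positive: int = 0
    by_tier: dict[str, int] = field(default_factory=dict)


def triage_cohort(
    cases: Sequence[PatientCase],
    snapshot: Snapshot,
    ontology: Ontology | None = None,
    config: RunConfig | None = None,
) -> tuple[list[Report], CohortSummary]:
    """One report per case plus summary counts (a partition of the cohort)."""
    reports = [triage_case(case, snapshot, ontology, config) for case in cases]
    summary = CohortSummary(n_cases=len(cases))
    for cat in ReportCategory:
        summary.by_category[cat.value] = 0
    for case, report in zip(cases, reports):
        summary.by_category[report.category.value] += 1
        for cv in case.variants:
            if cv.tier is not None:
                summary.by_tier[cv.tier.value] = summary.by_tier.get(cv.tier.value, 0) + 1
        if report.category is ReportCategory.POSITIVE:
            summary.reported_variants_in_positive += len(
                report.variants_with_role(VariantRole.PRIMARY, VariantRole.COMP_HET_PARTNER)
            )
        else:
            summary.vus_in_non_positive += sum(
                1 for cv in case.variants if cv.tier is Tier.VUS
            )
    return reports, summary


def flag_secondary_findings(
    case: PatientCase, report: Report, sf_gene_list: Iterable[str]
) -> Report:
    """Annotate P/LP variants in the configured gene list as secondary
    findings; flags never change the report category."""
    genes = {normalize_gene(g) for g in sf_gene_list}
    already = {rv.variant_key for rv in report.reported_variants}
    for cv in case.variants:
        if not cv.is_plp:
            continue
        if normalize_gene(cv.variant.gene_symbol) not in genes:
            continue
        key = cv.variant.key
        report.reported_variants.append(
            ReportedVariant(key, VariantRole.SECONDARY_FINDING, cv.tier, "")  # type: ignore[arg-type]
        )
        if key not in already:
            report.rule_citations.append(
                f"secondary finding in medically actionable gene "
                f"{normalize_gene(cv.variant.gene_symbol)}"
            )
    return report
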