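"""Readers and writers for the formats the pipeline touches.

Patient variants come in either as a minimal VCF (annotations in INFO keys
GENE / TRANSCRIPT / HGVSC / optional HGVSP; zygosity derived from GT) or as
a TSV mirroring a clinical report table.  Snapshot files are handled by
:mod:`retriage.knowledge_base`; ontologies by :mod:`retriage.phenotype`.
TSV dialects are tab-separated UTF-8 with '#' comment lines; JSON outputs
are key-sorted for diffability.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

from .acmg import CriterionAssignment, Strength, Tier, VariantClassification
from .config import SchemaError
from .knowledge_base import (
    GeneDiseaseEntry,
    Inheritance,
    Registration,
    Snapshot,
    is_omim_id,
)
from .triage import ClassifiedVariant, PatientCase, Report
from .variant_model import AlleleOrigin, Variant, Zygosity

logger = logging.getLogger(__name__)

#: snapshot date attached to the packaged report-table fixture (end of the
#: reanalysis window it was reported under)
FIXTURE_SNAPSHOT_DATE = dt.date(2021, 10, 31)
#: placeholder profile for fixture entries whose HPO profile is not printed;
#: triage of the fixture runs with the phenotype fit assumed satisfied
FIXTURE_PLACEHOLDER_TERM = "HP:0000118"


def fixture_path(name: str) -> Path:
    return Path(str(resources.files("retriage") / "fixtures" / name))


# ---------------------------------------------------------------------------
# Patient variants
# ---------------------------------------------------------------------------

_TSV_REQUIRED = ("patient_id", "gene", "zygosity", "transcript", "hgvs_c")


def read_patient_variants(path: str | Path) -> list[Variant]:
    """Read patient variants from VCF (``.vcf``) or TSV.

    Unparseable HGVS strings are kept (consequence ``other``) with a logged
    warning; rows missing mandatory columns raise :class:`SchemaError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return [v for v, _row in _read_tsv_rows(path)]


def _read_tsv_rows(path: Path) -> list[tuple[Variant, dict]]:
    out: list[tuple[Variant, dict]] = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        raise SchemaError(f"{path}: empty file")
    missing = set(_TSV_REQUIRED) - set(reader.fieldnames)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    n_unparsed = 0
    for lineno, row in enumerate(reader, start=2):
        try:
            variant = Variant(
                patient_id=row["patient_id"].strip(),
                gene_symbol=row["gene"].strip(),
                transcript=row["transcript"].strip(),
                hgvs_c=row["hgvs_c"].strip(),
                zygosity=Zygosity.parse(row["zygosity"]),
                allele_origin=AlleleOrigin.parse(row.get("allele_origin") or "unknown"),
                hgvs_p=(row.get("hgvs_p") or "").strip() or None,
            )
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: {exc}") from None
        if variant.parse_failed:
            n_unparsed += 1
            logger.warning(
                "%s:%d: unparseable HGVS %r kept with consequence 'other'",
                path, lineno, variant.hgvs_c,
            )
        out.append((variant, row))
    if n_unparsed:
        logger.warning("%s: %d of %d rows had unparseable HGVS", path, n_unparsed, len(out))
    return out


def _read_vcf(path: Path) -> list[Variant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    out: list[Variant] = []
    for record in vcf:
        info = dict(record.INFO)
        for key in ("GENE", "TRANSCRIPT", "HGVSC"):
            if key not in info:
                raise SchemaError(
                    f"{path}: record {record.CHROM}:{record.POS} missing INFO/{key}"
                )
        for i, sample in enumerate(samples or ["SAMPLE"]):
            if samples:
                alleles = record.genotypes[i][:-1]
                alts = [a for a in alleles if a > 0]
                if not alts:
                    continue
                if len(alleles) == 1:
                    zygosity = Zygosity.HEMIZYGOUS
                elif len(alts) == len(alleles):
                    zygosity = Zygosity.HOMOZYGOUS
                else:
                    zygosity = Zygosity.HETEROZYGOUS
            else:  # sites-only VCF: assume het
                zygosity = Zygosity.HETEROZYGOUS
            out.append(
                Variant(
                    patient_id=sample,
                    gene_symbol=str(info["GENE"]),
                    transcript=str(info["TRANSCRIPT"]),
                    hgvs_c=str(info["HGVSC"]),
                    zygosity=zygosity,
                    hgvs_p=str(info["HGVSP"]) if "HGVSP" in info else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Report-table fixture: cases with asserted classes plus a companion snapshot
# ---------------------------------------------------------------------------


def _classification_from_row(row: dict) -> VariantClassification:
    tier = Tier(row["class"].strip())
    assignments: tuple[CriterionAssignment, ...] = ()
    if tier is Tier.VUS:
        count = int(row.get("moderate_criteria") or 0)
        codes = ("PM3", "PM1", "PM4", "PM6")[:count]
        assignments = tuple(
            CriterionAssignment(code, Strength.MODERATE,
                                "moderate criterion transcribed from report")
            for code in codes
        )
    return VariantClassification(tier=tier, assignments=assignments)


def read_report_table(
    path: str | Path | None = None,
) -> tuple[list[PatientCase], Snapshot]:
    """Load a report-table TSV (the packaged 49-variant fixture by default).

    Returns the cases, each variant carrying its asserted classification,
    plus a companion snapshot holding one gene-disease entry per distinct
    (gene, disease_id) in the table.  Entry HPO profiles are not printed in
    such tables, so triage runs on them with ``assume_phenotype_fit``.
    """
    path = Path(path) if path is not None else fixture_path("table2.tsv")
    rows = _read_tsv_rows(path)
    cases: dict[str, PatientCase] = {}
    entries: dict[tuple[str, str], GeneDiseaseEntry] = {}
    for variant, row in rows:
        case = cases.setdefault(
            variant.patient_id, PatientCase(patient_id=variant.patient_id)
        )
        case.variants.append(
            ClassifiedVariant(variant, _classification_from_row(row))
        )
        disease_id = row["disease_id"].strip()
        key = (variant.gene_symbol, disease_id)
        if key not in entries:
            entries[key] = GeneDiseaseEntry(
                gene_symbol=variant.gene_symbol,
                disease_id=disease_id,
                disease_name=row.get("disease_name", "").strip(),
                inheritance=Inheritance.parse(row["inheritance"]),
                registration=(
                    Registration.OMIM_REGISTERED
                    if is_omim_id(disease_id)
                    else Registration.LITERATURE_CANDIDATE
                ),
                hpo_profile=frozenset({FIXTURE_PLACEHOLDER_TERM}),
                entry_date=FIXTURE_SNAPSHOT_DATE,
            )
    snapshot = Snapshot(
        snapshot_date=FIXTURE_SNAPSHOT_DATE, entries=entries
    ).validate()
    return list(cases.values()), snapshot


def read_gene_list(path: str | Path) -> list[str]:
    """One-column text config (e.g. the secondary-findings gene list)."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------


def report_to_dict(report: Report) -> dict:
    return {
        "patient_id": report.patient_id,
        "category": report.category.value,
        "report_date": report.report_date.isoformat() if report.report_date else None,
        "reported_variants": [
            {
                "variant_key": rv.variant_key,
                "role": rv.role.value,
                "tier": rv.tier.value,
                "disease_id": rv.disease_id,
            }
            for rv in report.reported_variants
        ],
        "rule_citations": list(report.rule_citations),
        "similarity_scores": {
            k: v for k, v in sorted(report.similarity_scores.items())
        },
    }


def write_reports_json(reports: Sequence[Report], path: str | Path) -> None:
    doc = [report_to_dict(r) for r in reports]
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def report_to_text(report: Report) -> str:
    """Plain-text narrative of one report."""
    lines = [
        f"Patient {report.patient_id} — report "
        f"{report.report_date.isoformat() if report.report_date else '(undated)'}",
        f"Result: {report.category.value.upper()}",
    ]
    if report.reported_variants:
        lines.append("Variants:")
        for rv in report.reported_variants:
            lines.append(f"  - {rv.variant_key} [{rv.tier.value}] ({rv.role.value})")
    else:
        lines.append("No clinically significant variant was identified.")
    for citation in report.rule_citations:
        lines.append(f"Rule: {citation}")
    for disease_id, score in sorted(report.similarity_scores.items()):
        if score is not None:
            lines.append(f"Similarity vs {disease_id}: {score:.2f}/10")
    return "\n".join(lines) + "\n"


def write_reports_text(reports: Sequence[Report], path: str | Path) -> None:
    Path(path).write_text("\n".join(report_to_text(r) for r in reports))
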