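"""The daily prospective reanalysis loop.

Each day a fresh knowledge-base snapshot arrives; the delta against the
previous day's snapshot decides which genes need a second look.  Variants
of still-undiagnosed cases in touched genes are re-classified and re-scored;
a :class:`ReclassificationEvent` is emitted when a variant newly becomes
P/LP, or becomes a VUS whose symptom-similarity score crosses the flagging
threshold under an evidence state not seen before.  A review ledger records
geneticists' confirm/exclude decisions: an excluded variant stays silent
until the evidence state it was reviewed under changes (tracked by a stable
fingerprint), mirroring "not relisted until a new change is detected".
Confirmed events update the case's report through the triage rules.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .acmg import EvidenceFacts, Tier, classify
from .config import DateOrderingError, RetriageError, RunConfig
from .knowledge_base import (
    AssertedClass,
    GeneDiseaseEntry,
    KBDelta,
    Snapshot,
)
from .phenotype import Ontology, similarity_score
from .config import EmptyPhenotypeError
from .triage import (
    ClassifiedVariant,
    PatientCase,
    Report,
    ReportCategory,
    triage_case,
)
from .variant_model import AlleleOrigin, Variant, Zygosity, normalize_gene

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class EventTrigger(str, Enum):
    NEW_GENE_DISEASE = "new_gene_disease"
    ASSERTION_UPDATE = "assertion_update"
    FREQUENCY_UPDATE = "frequency_update"
    PHENOTYPE_UPDATE = "phenotype_update"


@dataclass(frozen=True)
class ReclassificationEvent:
    patient_id: str
    variant_key: str
    old_tier: Tier | None
    new_tier: Tier
    similarity_score: float | None
    trigger: EventTrigger
    event_date: dt.date
    disease_id: str = ""
    evidence_fingerprint: str = ""


class ReviewDecision(str, Enum):
    CONFIRMED = "confirmed"
    EXCLUDED = "excluded"


@dataclass
class LedgerEntry:
    decision: ReviewDecision
    decision_date: dt.date
    evidence_fingerprint: str


@dataclass
class ReviewLedger:
    """Review decisions keyed by (patient_id, variant_key)."""

    entries: dict[tuple[str, str], LedgerEntry] = field(default_factory=dict)

    def get(self, patient_id: str, variant_key: str) -> LedgerEntry | None:
        return self.entries.get((patient_id, variant_key))

    def record(
        self,
        patient_id: str,
        variant_key: str,
        decision: ReviewDecision,
        decision_date: dt.date,
        fingerprint: str,
    ) -> None:
        self.entries[(patient_id, variant_key)] = LedgerEntry(
            decision, decision_date, fingerprint
        )

    def to_json(self, path: str | Path) -> None:
        doc = [
            {
                "patient_id": pid,
                "variant_key": key,
                "decision": e.decision.value,
                "decision_date": e.decision_date.isoformat(),
                "evidence_fingerprint": e.evidence_fingerprint,
            }
            for (pid, key), e in sorted(self.entries.items())
        ]
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReviewLedger":
        ledger = cls()
        for rec in json.loads(Path(path).read_text()):
            ledger.record(
                rec["patient_id"],
                rec["variant_key"],
                ReviewDecision(rec["decision"]),
                dt.date.fromisoformat(rec["decision_date"]),
                rec["evidence_fingerprint"],
            )
        return ledger


# ---------------------------------------------------------------------------
# Evidence assembly
# ---------------------------------------------------------------------------


def _frequency_bin(af: float | None, boundaries: Sequence[float]) -> int:
    """Index of the criterion band an allele frequency falls in (-1: absent)."""
    if af is None:
        return -1
    return int(sum(af > b for b in boundaries))


def build_facts(
    variant: Variant,
    case: PatientCase,
    snapshot: Snapshot,
    entry: GeneDiseaseEntry,
    plp_partner_keys: frozenset[str] = frozenset(),
    config: RunConfig | None = None,
) -> EvidenceFacts:
    """Assemble the structured evidence for one variant from a snapshot.

    ``plp_partner_keys`` are variant keys in the same gene already known to
    be P/LP; the in-trans flag is only set when phase is actually known
    (homozygosity or trans-confirmed segregation).
    """
    key = variant.key
    assertion = snapshot.assertions.get(key)
    same_residue = None
    residue = variant.protein_residue
    if residue is not None:
        for a in snapshot.assertions.values():
            if (
                a.variant_key != key
                and a.protein_residue == residue
                and a.variant_key.startswith(normalize_gene(variant.gene_symbol) + "|")
                and a.asserted_class is AssertedClass.P
            ):
                same_residue = a
                break
    in_trans = variant.zygosity is Zygosity.HOMOZYGOUS or (
        variant.allele_origin is AlleleOrigin.TRANS_CONFIRMED
        and bool(plp_partner_keys - {key})
    )
    kwargs: dict = dict(
        population_af=snapshot.frequencies.get(key),
        population_absent=key not in snapshot.frequencies,
        lof_mechanism=entry.lof_mechanism,
        matching_assertion=assertion,
        same_residue_assertion=same_residue,
        de_novo=variant.allele_origin is AlleleOrigin.ASSUMED_DE_NOVO,
        in_trans_with_plp=in_trans,
    )
    kwargs.update(case.evidence_notes.get(key, {}))
    return EvidenceFacts(**kwargs)


def evidence_fingerprint(
    variant: Variant,
    case: PatientCase,
    snapshot: Snapshot,
    entry: GeneDiseaseEntry,
    config: RunConfig | None = None,
) -> str:
    """Stable hash of the evidence state a review decision applies to.

    Covers the matching and same-residue assertions, the entry's curated
    fields, the criterion band of the population frequency and the patient's
    phenotype terms — i.e. everything whose change counts as "a new change
    was detected"."""
    config = config or RunConfig()
    key = variant.key
    assertion = snapshot.assertions.get(key)
    payload = {
        "assertion": (
            [assertion.asserted_class.value, assertion.source]
            if assertion
            else None
        ),
        "entry": [
            entry.gene_symbol,
            entry.disease_id,
            entry.inheritance.value,
            entry.registration.value,
            sorted(entry.hpo_profile),
            entry.entry_date.isoformat(),
        ],
        "frequency_bin": _frequency_bin(
            snapshot.frequencies.get(key), config.frequency_boundaries
        ),
        "patient_terms": sorted(case.hpo_terms),
        "notes": case.evidence_notes.get(key, {}) and sorted(
            (k, str(v)) for k, v in case.evidence_notes[key].items()
        ),
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    return digest[:16]


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


def eligible_cases(
    cases_with_reports: Iterable[tuple[PatientCase, Report]],
) -> list[PatientCase]:
    """Cases that stay on the daily reanalysis queue.

    All cases whose latest report is negative or inconclusive (VUS-only
    findings, potential compound hets with a weak VUS, multiple VUS, or
    P/LP findings still pending OMIM registration or phenotype confirmation)
    remain eligible; positively diagnosed cases leave the queue.
    """
    return [
        case
        for case, report in cases_with_reports
        if report.category is not ReportCategory.POSITIVE
    ]


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------


@dataclass
class _FlagState:
    """Last emitted evidence fingerprint per (patient, variant)."""

    emitted: dict[tuple[str, str], str] = field(default_factory=dict)


class ReanalysisEngine:
    """Holds the cohort, ledger and emission state across daily runs.

    With ``auto_confirm`` (simulation mode) every emitted event is treated
    as review-confirmed and reports are updated immediately; otherwise
    events stay pending until :meth:`record_review`.
    """

    def __init__(
        self,
        cases: Sequence[PatientCase],
        ontology: Ontology | None = None,
        config: RunConfig | None = None,
        ledger: ReviewLedger | None = None,
        auto_confirm: bool = False,
    ) -> None:
        self.cases = list(cases)
        self.by_patient = {c.patient_id: c for c in self.cases}
        self.ontology = ontology
        self.config = config or RunConfig()
        self.ledger = ledger or ReviewLedger()
        self.auto_confirm = auto_confirm
        self.events: list[ReclassificationEvent] = []
        self._flags = _FlagState()
        self._pending: dict[tuple[str, str], ReclassificationEvent] = {}

    # -- helpers -----------------------------------------------------------

    def _undiagnosed(self) -> list[PatientCase]:
        return [
            c
            for c in self.cases
            if c.latest_report is None
            or c.latest_report.category is not ReportCategory.POSITIVE
        ]

    def triage_all(self, snapshot: Snapshot, date: dt.date | None = None) -> list[Report]:
        """First reports for every case that has none yet."""
        out = []
        for case in self.cases:
            if case.report_history:
                continue
            report = triage_case(case, snapshot, self.ontology, self.config, date)
            case.report_history.append(report)
            out.append(report)
        return out

    def _best_entry_view(
        self, case: PatientCase, cv: ClassifiedVariant, snapshot: Snapshot
    ) -> tuple[GeneDiseaseEntry, Tier, tuple, float | None] | None:
        """Classify ``cv`` under every entry of its gene; keep the most
        pathogenic (tier, then score) view."""
        gene = normalize_gene(cv.variant.gene_symbol)
        entries = snapshot.entries_for_gene(gene)
        if not entries:
            return None
        plp_partner_keys = frozenset(
            other.variant.key
            for other in case.variants
            if other is not cv
            and normalize_gene(other.variant.gene_symbol) == gene
            and (
                other.is_plp
                or (
                    (a := snapshot.assertions.get(other.variant.key)) is not None
                    and a.asserted_class in (AssertedClass.P, AssertedClass.LP)
                )
            )
        )
        tier_rank = {Tier.P: 4, Tier.LP: 3, Tier.VUS: 2, Tier.LB: 1, Tier.B: 0}
        best = None
        for entry in sorted(entries, key=lambda e: e.disease_id):
            facts = build_facts(
                cv.variant, case, snapshot, entry, plp_partner_keys, self.config
            )
            classification = classify(
                cv.variant, facts, entry, self.config, snapshot.snapshot_date
            )
            score: float | None = None
            if self.config.assume_phenotype_fit or self.ontology is None:
                score = None
            else:
                try:
                    score = similarity_score(
                        case.hpo_terms, entry.hpo_profile, self.ontology
                    ).score
                except EmptyPhenotypeError:
                    score = 0.0
            rank = (tier_rank[classification.tier], score if score is not None else 10.0)
            if best is None or rank > best[0]:
                best = (rank, entry, classification, score)
        assert best is not None
        _, entry, classification, score = best
        return entry, classification.tier, classification.assignments, score

    def _trigger_for(
        self, delta: KBDelta | None, entry: GeneDiseaseEntry, key: str, gene: str
    ) -> EventTrigger:
        if delta is None:
            return EventTrigger.PHENOTYPE_UPDATE
        if any(e.key == entry.key for e in delta.added_entries):
            return EventTrigger.NEW_GENE_DISEASE
        if any(a.variant_key == key for a in delta.changed_or_added_assertions):
            return EventTrigger.ASSERTION_UPDATE
        if key in delta.changed_frequencies:
            return EventTrigger.FREQUENCY_UPDATE
        if any(e.gene_symbol == gene for e in delta.added_entries):
            return EventTrigger.NEW_GENE_DISEASE
        if any(
            a.variant_key.startswith(gene + "|")
            for a in delta.changed_or_added_assertions
        ):
            return EventTrigger.ASSERTION_UPDATE
        return EventTrigger.FREQUENCY_UPDATE

    # -- the daily loop ----------------------------------------------------

    def daily_run(
        self,
        delta: KBDelta,
        new_snapshot: Snapshot,
        run_date: dt.date | None = None,
        full_scan: bool | None = None,
    ) -> list[ReclassificationEvent]:
        """React to one day's knowledge-base delta.

        Only variants in genes touched by the delta are re-evaluated unless
        ``full_scan``; rerunning with the same delta and ledger is a no-op.
        """
        run_date = run_date or new_snapshot.snapshot_date
        if new_snapshot.snapshot_date != delta.new_date:
            raise DateOrderingError(
                f"delta ends {delta.new_date} but snapshot is dated "
                f"{new_snapshot.snapshot_date}"
            )
        if run_date < new_snapshot.snapshot_date:
            raise DateOrderingError(
                f"run date {run_date} precedes snapshot {new_snapshot.snapshot_date}"
            )
        full = self.config.full_scan if full_scan is None else full_scan
        touched = {normalize_gene(g) for g in delta.affected_genes}
        if not full and not touched:
            return []
        emitted: list[ReclassificationEvent] = []
        for case in self._undiagnosed():
            case_events = []
            for cv in case.variants:
                gene = normalize_gene(cv.variant.gene_symbol)
                if not full and gene not in touched:
                    continue
                event = self._reevaluate(case, cv, new_snapshot, delta, run_date)
                if event is not None:
                    case_events.append(event)
            emitted.extend(case_events)
            if case_events and self.auto_confirm:
                for ev in case_events:
                    self._confirm(ev, new_snapshot, run_date)
        self.events.extend(emitted)
        return emitted

    def _reevaluate(
        self,
        case: PatientCase,
        cv: ClassifiedVariant,
        snapshot: Snapshot,
        delta: KBDelta | None,
        run_date: dt.date,
        trigger_override: EventTrigger | None = None,
    ) -> ReclassificationEvent | None:
        view = self._best_entry_view(case, cv, snapshot)
        if view is None:
            return None
        entry, new_tier, assignments, score = view
        old_tier = cv.tier
        pid = case.patient_id
        key = cv.variant.key

        # keep the stored classification current regardless of emission
        from .acmg import VariantClassification

        cv.classification = VariantClassification(
            tier=new_tier, assignments=assignments, classified_on=run_date
        )

        qualifies_plp = new_tier in (Tier.P, Tier.LP)
        flag_ok = score is None or score >= self.config.similarity_threshold
        qualifies_vus = new_tier is Tier.VUS and score is not None and flag_ok
        if not (qualifies_plp or qualifies_vus):
            return None

        fp = evidence_fingerprint(cv.variant, case, snapshot, entry, self.config)
        led = self.ledger.get(pid, key)
        if led is not None:
            if led.evidence_fingerprint == fp:
                return None  # reviewed under this exact evidence state
            # evidence changed since review: excluded variants re-surface
        else:
            novel = (qualifies_plp and new_tier != old_tier) or (
                qualifies_vus and self._flags.emitted.get((pid, key)) != fp
            )
            if not novel:
                return None

        trigger = trigger_override or self._trigger_for(delta, entry, key, cv.variant.gene_symbol)
        event = ReclassificationEvent(
            patient_id=pid,
            variant_key=key,
            old_tier=old_tier,
            new_tier=new_tier,
            similarity_score=score,
            trigger=trigger,
            event_date=run_date,
            disease_id=entry.disease_id,
            evidence_fingerprint=fp,
        )
        self._flags.emitted[(pid, key)] = fp
        self._pending[(pid, key)] = event
        return event

    # -- review ------------------------------------------------------------

    def record_review(
        self,
        event: ReclassificationEvent,
        decision: ReviewDecision,
        snapshot: Snapshot,
        decision_date: dt.date | None = None,
    ) -> ReviewLedger:
        """Store a geneticist's decision for a previously emitted event."""
        pid, key = event.patient_id, event.variant_key
        if self._pending.get((pid, key)) is not event and event not in self.events:
            raise RetriageError(
                f"decision for unknown event ({pid}, {key}); emit it first"
            )
        date = decision_date or event.event_date
        self.ledger.record(pid, key, decision, date, event.evidence_fingerprint)
        if decision is ReviewDecision.CONFIRMED:
            self._confirm(event, snapshot, date)
        return self.ledger

    def _confirm(
        self, event: ReclassificationEvent, snapshot: Snapshot, date: dt.date
    ) -> None:
        case = self.by_patient[event.patient_id]
        report = triage_case(case, snapshot, self.ontology, self.config, date)
        previous = case.latest_report
        if previous is None or report.category != previous.category or (
            report.reported_variants != previous.reported_variants
        ):
            case.report_history.append(report)

    # -- phenotype updates --------------------------------------------------

    def phenotype_update(
        self,
        case: PatientCase,
        added_terms: Iterable[str],
        snapshot: Snapshot,
        run_date: dt.date,
    ) -> list[ReclassificationEvent]:
        """Re-score a case after physicians submit additional phenotype terms."""
        added = set(added_terms)
        if not added:
            raise RetriageError("phenotype_update requires at least one term")
        if self.ontology is not None:
            known = {t for t in added if t in self.ontology}
            if not known:
                logger.warning(
                    "patient %s: all submitted terms unknown; phenotype unchanged",
                    case.patient_id,
                )
                return []
            dropped = added - known
            if dropped:
                logger.warning(
                    "patient %s: dropping unknown terms %s",
                    case.patient_id,
                    sorted(dropped),
                )
            added = known
        case.hpo_terms = frozenset(case.hpo_terms | added)
        latest = case.latest_report
        if latest is not None and latest.category is ReportCategory.POSITIVE:
            return []
        emitted = []
        for cv in case.variants:
            event = self._reevaluate(
                case,
                cv,
                snapshot,
                None,
                run_date,
                trigger_override=EventTrigger.PHENOTYPE_UPDATE,
            )
            if event is not None:
                emitted.append(event)
        self.events.extend(emitted)
        if emitted and self.auto_confirm:
            for ev in emitted:
                self._confirm(ev, snapshot, run_date)
        return emitted


# ---------------------------------------------------------------------------
# Cohort metrics
# ---------------------------------------------------------------------------


@dataclass
class CohortMetrics:
    daily_variant_counts: dict[dt.date, int]
    daily_patient_counts: dict[dt.date, int]
    variants_per_day_mean: float
    variants_per_day_sd: float
    patients_per_day_mean: float
    patients_per_day_sd: float
    cumulative_diagnosed: list[tuple[dt.date, int]]
    intervals_years: list[float]
    interval_mean_years: float
    interval_sd_years: float


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        return float("nan"), float("nan")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def cohort_metrics(
    events: Sequence[ReclassificationEvent],
    reports: Sequence[Report],
) -> CohortMetrics:
    """Per-day event counts (days with >= 1 event), the cumulative diagnosed
    curve, and time-to-diagnosis (first report to confirming event, in
    365.25-day years)."""
    first_report: dict[str, dt.date] = {}
    positive_date: dict[str, dt.date] = {}
    for r in reports:
        if r.report_date is None:
            continue
        pid = r.patient_id
        if pid not in first_report or r.report_date < first_report[pid]:
            first_report[pid] = r.report_date
        if r.category is ReportCategory.POSITIVE and pid not in positive_date:
            positive_date[pid] = r.report_date

    daily_v: dict[dt.date, int] = {}
    daily_p: dict[dt.date, set[str]] = {}
    for ev in events:
        pid = ev.patient_id
        if pid in first_report and ev.event_date < first_report[pid]:
            raise RetriageError(
                f"event for {pid} on {ev.event_date} precedes first report "
                f"{first_report[pid]}"
            )
        daily_v[ev.event_date] = daily_v.get(ev.event_date, 0) + 1
        daily_p.setdefault(ev.event_date, set()).add(pid)

    v_mean, v_sd = _mean_sd(list(daily_v.values()))
    p_mean, p_sd = _mean_sd([len(s) for s in daily_p.values()])

    cumulative: list[tuple[dt.date, int]] = []
    for i, d in enumerate(sorted(positive_date.values())):
        cumulative.append((d, i + 1))

    intervals = [
        (positive_date[pid] - first_report[pid]).days / DAYS_PER_YEAR
        for pid in positive_date
        if pid in first_report and positive_date[pid] > first_report[pid]
    ]
    i_mean, i_sd = _mean_sd(intervals)
    return CohortMetrics(
        daily_variant_counts=daily_v,
        daily_patient_counts={d: len(s) for d, s in daily_p.items()},
        variants_per_day_mean=v_mean,
        variants_per_day_sd=v_sd,
        patients_per_day_mean=p_mean,
        patients_per_day_sd=p_sd,
        cumulative_diagnosed=cumulative,
        intervals_years=sorted(intervals),
        interval_mean_years=i_mean,
        interval_sd_years=i_sd,
    )


def write_event_log(
    events: Sequence[ReclassificationEvent], path: str | Path
) -> None:
    """Append-only TSV event log."""
    lines = [
        "#date\tpatient_id\tvariant_key\told_tier\tnew_tier\tscore\ttrigger"
    ]
    for ev in events:
        lines.append(
            "\t".join(
                (
                    ev.event_date.isoformat(),
                    ev.patient_id,
                    ev.variant_key,
                    ev.old_tier.value if ev.old_tier else ".",
                    ev.new_tier.value,
                    f"{ev.similarity_score:.4f}" if ev.similarity_score is not None else ".",
                    ev.trigger.value,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_log(path: str | Path) -> list[dict]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        date, pid, key, old, new, score, trigger = line.split("\t")
        out.append(
            {
                "event_date": dt.date.fromisoformat(date),
                "patient_id": pid,
                "variant_key": key,
                "old_tier": None if old == "." else Tier(old),
                "new_tier": Tier(new),
                "similarity_score": None if score == "." else float(score),
                "trigger": EventTrigger(trigger),
            }
        )
    return out
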