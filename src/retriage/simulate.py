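"""Synthetic patients, variants and an evolving knowledge-base timeline.

The generator plants discoverable diagnoses: a configurable fraction of
patients carry a causal variant whose gene-disease entry is either already
curated at the start of the timeline or enters the knowledge base on a
known later date.  Background gene discoveries and variant assertions
arrive as Poisson processes at the literature-scale default rates of about
250 new gene-disease and 9200 new variant-disease associations per year,
so the daily deltas the reanalysis loop sees have a realistic shape.
Because every planted diagnosis has a known discovery date, a replay can be
scored exactly: recall, anticipation (diagnoses before the enabling
knowledge exists) and per-patient delay.

Phenotypes are drawn from a programmatically built toy ontology (a
balanced 4-level DAG of 156 terms) and a 50-disease corpus; patient term
counts for background patients follow the cohort-scale mean of 8.6 +/- 4.6
terms.  The generator makes no attempt at realistic human allele-frequency
spectra.
"""
from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .config import RunConfig
from .knowledge_base import (
    AssertedClass,
    GeneDiseaseEntry,
    Inheritance,
    Registration,
    Snapshot,
    VariantAssertion,
    diff_snapshots,
)
from .phenotype import Ontology
from .reanalysis import ReanalysisEngine, ReclassificationEvent
from .triage import ClassifiedVariant, PatientCase, ReportCategory
from .variant_model import AlleleOrigin, Variant, Zygosity, variant_key

DAYS_PER_YEAR = 365.25


@dataclass
class SimulationConfig:
    n_patients: int = 100
    start_date: dt.date = dt.date(2019, 4, 1)
    timeline_days: int = 730
    #: enrollment waves as (first_day, last_day) offsets into the timeline;
    #: patients are distributed evenly across waves, uniformly within each.
    #: Default: one wave over the first year (or the whole timeline if shorter)
    enrollment_waves: tuple[tuple[int, int], ...] | None = None
    gene_discovery_rate: float = 250.0  # background, per year
    variant_assertion_rate: float = 9200.0  # background, per year
    frac_causal: float = 0.7
    frac_undiscovered: float = 0.5  # of causal genes, not yet curated at day 0
    frac_recessive: float = 0.2  # of causal patients, biallelic mechanism
    phenotype_drop_rate: float = 0.0  # per profile term
    phenotype_add_mean: float = 0.0  # Poisson mean of random extra terms
    mean_hpo_terms: float = 8.6  # background patients
    sd_hpo_terms: float = 4.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.timeline_days < 1:
            raise ValueError("n_patients and timeline_days must be positive")
        for name in ("frac_causal", "frac_undiscovered", "frac_recessive",
                     "phenotype_drop_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.gene_discovery_rate, self.variant_assertion_rate,
               self.phenotype_add_mean) < 0:
            raise ValueError("rates must be nonnegative")
        if self.enrollment_waves is None:
            self.enrollment_waves = ((0, min(365, self.timeline_days)),)
        self.enrollment_waves = tuple(tuple(w) for w in self.enrollment_waves)
        for lo, hi in self.enrollment_waves:
            if not (0 <= lo <= hi <= self.timeline_days):
                raise ValueError("enrollment waves must lie within the timeline")


@dataclass
class PatientTruth:
    patient_id: str
    causal_variant_key: str | None
    entry: GeneDiseaseEntry | None
    discovery_date: dt.date | None  # None: curated before day 0, or no variant
    expected_final_category: ReportCategory

    @property
    def diagnosable(self) -> bool:
        return self.entry is not None


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    cases: list[PatientCase]
    ground_truth: dict[str, PatientTruth]
    ontology: Ontology
    #: planted entries already curated at day 0
    initial_entries: list[GeneDiseaseEntry]
    #: planted entries by discovery date
    pending_entries: dict[dt.date, list[GeneDiseaseEntry]]
    #: constant allele frequencies for non-causal variants
    frequencies: dict[str, float]


# ---------------------------------------------------------------------------
# Toy ontology and disease corpus
# ---------------------------------------------------------------------------


def build_toy_ontology(
    rng: np.random.Generator,
    n_diseases: int = 50,
    branching: int = 5,
    depth: int = 3,
    profile_size: tuple[int, int] = (5, 9),
) -> Ontology:
    """Balanced DAG (1 + 5 + 25 + 125 = 156 terms) with a disease corpus.

    Each disease lives mostly inside one top-level branch so that profiles
    of different diseases are semantically separated.
    """
    graph = nx.DiGraph()
    counter = itertools.count(1)
    root = f"HP:{next(counter):07d}"
    graph.add_node(root)
    levels: list[list[str]] = [[root]]
    for _ in range(depth):
        nxt: list[str] = []
        for parent in levels[-1]:
            for _ in range(branching):
                term = f"HP:{next(counter):07d}"
                graph.add_edge(term, parent)  # child -> parent
                nxt.append(term)
        levels.append(nxt)
    leaves = levels[-1]
    leaves_per_branch = len(leaves) // branching

    annotations: dict[str, list[str]] = {}
    for i in range(n_diseases):
        branch = i % branching
        pool = leaves[branch * leaves_per_branch : (branch + 1) * leaves_per_branch]
        size = int(rng.integers(profile_size[0], profile_size[1] + 1))
        terms = list(rng.choice(pool, size=min(size, len(pool)), replace=False))
        annotations[f"6{i:05d}"] = terms
    return Ontology(graph, annotations)


# ---------------------------------------------------------------------------
# Variant templates (one per consequence category the classifier knows)
# ---------------------------------------------------------------------------


def _causal_hgvs(rng: np.random.Generator) -> tuple[str, str | None]:
    """A loss-of-function style description (classifies via PVS1)."""
    pos = int(rng.integers(100, 3000))
    kind = int(rng.integers(0, 4))
    if kind == 0:
        return f"c.{pos}del", None  # frameshift
    if kind == 1:
        return f"c.{pos}_{pos + 3}del", None  # frameshift (4 nt)
    if kind == 2:
        return f"c.{pos}-2A>G", None  # canonical splice
    return f"c.{pos}G>A", f"p.Trp{pos // 3}Ter"  # stop gain


def _background_hgvs(rng: np.random.Generator) -> tuple[str, str | None]:
    pos = int(rng.integers(100, 3000))
    return f"c.{pos}C>T", None  # unresolved substitution


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _phenotype_from_profile(
    profile: Sequence[str],
    ontology: Ontology,
    rng: np.random.Generator,
    drop_rate: float,
    add_mean: float,
) -> frozenset[str]:
    kept = [t for t in profile if rng.random() >= drop_rate]
    if not kept:
        kept = [profile[int(rng.integers(0, len(profile)))]]
    n_extra = int(rng.poisson(add_mean)) if add_mean > 0 else 0
    if n_extra:
        leaves = [t for t in ontology.graph.nodes if ontology.graph.in_degree(t) == 0]
        kept += list(rng.choice(leaves, size=n_extra, replace=False))
    return frozenset(kept)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Deterministic (under ``config.seed``) cohort with planted truths."""
    ss = np.random.SeedSequence(config.seed)
    rng_onto, rng_cohort, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    ontology = build_toy_ontology(rng_onto)
    disease_ids = sorted(ontology.diseases)
    leaves = sorted(
        t for t in ontology.graph.nodes if ontology.graph.in_degree(t) == 0
    )

    start = config.start_date
    wave_list = list(config.enrollment_waves)
    cases: list[PatientCase] = []
    truths: dict[str, PatientTruth] = {}
    initial_entries: list[GeneDiseaseEntry] = []
    pending: dict[dt.date, list[GeneDiseaseEntry]] = {}
    frequencies: dict[str, float] = {}

    for i in range(config.n_patients):
        pid = f"SIM{i:04d}"
        lo, hi = wave_list[i % len(wave_list)]
        enroll = start + dt.timedelta(days=int(rng_cohort.integers(lo, hi + 1)))
        causal = rng_cohort.random() < config.frac_causal
        case = PatientCase(patient_id=pid, enrollment_date=enroll)

        if not causal:
            n_terms = max(
                1,
                min(
                    len(leaves),
                    int(round(rng_cohort.normal(config.mean_hpo_terms,
                                                config.sd_hpo_terms))),
                ),
            )
            case.hpo_terms = frozenset(
                rng_cohort.choice(leaves, size=n_terms, replace=False)
            )
            gene = f"BGGENE{i:04d}"
            hgvs, hgvs_p = _background_hgvs(rng_cohort)
            v = Variant(pid, gene, "NM_900000.1", hgvs, Zygosity.HETEROZYGOUS,
                        AlleleOrigin.UNKNOWN, hgvs_p)
            # common enough to fail PM2 everywhere, too rare for BA1
            frequencies[v.key] = 5e-4
            case.variants.append(ClassifiedVariant(v))
            cases.append(case)
            truths[pid] = PatientTruth(pid, None, None, None,
                                       ReportCategory.NEGATIVE)
            continue

        disease_id = disease_ids[i % len(disease_ids)]
        profile = sorted(ontology.diseases[disease_id])
        recessive = rng_cohort.random() < config.frac_recessive
        gene = f"CAUSAL{i:04d}"
        inheritance = Inheritance.AR if recessive else Inheritance.AD
        undiscovered = rng_cohort.random() < config.frac_undiscovered
        if undiscovered:
            day = int(rng_cohort.integers(1, config.timeline_days + 1))
            discovery: dt.date | None = start + dt.timedelta(days=day)
            entry_date = discovery
        else:
            discovery = None
            entry_date = start - dt.timedelta(days=int(rng_cohort.integers(30, 400)))
        entry = GeneDiseaseEntry(
            gene_symbol=gene,
            disease_id=f"{int(disease_id) + 300000 + i}",  # unique per patient-gene
            disease_name=f"synthetic disorder {i}",
            inheritance=inheritance,
            registration=Registration.OMIM_REGISTERED,
            hpo_profile=frozenset(profile),
            entry_date=entry_date,
        )
        if discovery is None:
            initial_entries.append(entry)
        else:
            pending.setdefault(discovery, []).append(entry)

        case.hpo_terms = _phenotype_from_profile(
            profile, ontology, rng_noise,
            config.phenotype_drop_rate, config.phenotype_add_mean,
        )
        transcript = "NM_800000.1"
        if recessive:
            hgvs_a, p_a = _causal_hgvs(rng_cohort)
            hgvs_b, p_b = _causal_hgvs(rng_cohort)
            if hgvs_b == hgvs_a:
                hgvs_b = f"c.{int(rng_cohort.integers(3001, 4000))}del"
                p_b = None
            homozygous = rng_cohort.random() < 0.5
            if homozygous:
                v = Variant(pid, gene, transcript, hgvs_a, Zygosity.HOMOZYGOUS,
                            AlleleOrigin.TRANS_CONFIRMED, p_a)
                case.variants.append(ClassifiedVariant(v))
                causal_key = v.key
            else:
                va = Variant(pid, gene, transcript, hgvs_a, Zygosity.HETEROZYGOUS,
                             AlleleOrigin.TRANS_CONFIRMED, p_a)
                vb = Variant(pid, gene, transcript, hgvs_b, Zygosity.HETEROZYGOUS,
                             AlleleOrigin.TRANS_CONFIRMED, p_b)
                case.variants += [ClassifiedVariant(va), ClassifiedVariant(vb)]
                # segregation in the family was informative for both alleles
                case.evidence_notes[va.key] = {"segregation_observed": True}
                case.evidence_notes[vb.key] = {"segregation_observed": True}
                causal_key = va.key
        else:
            hgvs, hgvs_p = _causal_hgvs(rng_cohort)
            v = Variant(pid, gene, transcript, hgvs, Zygosity.HETEROZYGOUS,
                        AlleleOrigin.ASSUMED_DE_NOVO, hgvs_p)
            case.variants.append(ClassifiedVariant(v))
            causal_key = v.key
        cases.append(case)
        truths[pid] = PatientTruth(pid, causal_key, entry, discovery,
                                   ReportCategory.POSITIVE)

    return SyntheticCohort(
        config=config,
        cases=cases,
        ground_truth=truths,
        ontology=ontology,
        initial_entries=initial_entries,
        pending_entries=pending,
        frequencies=frequencies,
    )


# ---------------------------------------------------------------------------
# Knowledge-base timeline
# ---------------------------------------------------------------------------


class KBTimeline:
    """Ordered daily snapshots, yielded lazily (state is cumulative)."""

    def __init__(self, config: SimulationConfig, cohort: SyntheticCohort) -> None:
        self.config = config
        self.cohort = cohort
        self.dates = [
            config.start_date + dt.timedelta(days=d)
            for d in range(config.timeline_days + 1)
        ]
        self.background_discoveries = 0
        self.background_assertions = 0

    def __iter__(self) -> Iterator[Snapshot]:
        config, cohort = self.config, self.cohort
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(4)[3]
        )
        gene_daily = config.gene_discovery_rate / DAYS_PER_YEAR
        assertion_daily = config.variant_assertion_rate / DAYS_PER_YEAR
        leaves = sorted(
            t for t in cohort.ontology.graph.nodes
            if cohort.ontology.graph.in_degree(t) == 0
        )
        entries: dict = {}
        assertions: dict = {}
        bg_gene = itertools.count()
        bg_assert = itertools.count()
        for e in cohort.initial_entries:
            entries[e.key] = e

        self.background_discoveries = 0
        self.background_assertions = 0
        for day, date in enumerate(self.dates):
            if day > 0:
                for e in cohort.pending_entries.get(date, ()):
                    entries[e.key] = e
                for _ in range(int(rng.poisson(gene_daily))):
                    i = next(bg_gene)
                    self.background_discoveries += 1
                    profile = frozenset(
                        rng.choice(leaves, size=5, replace=False)
                    )
                    e = GeneDiseaseEntry(
                        gene_symbol=f"FILLER{i:05d}",
                        disease_id=f"7{i:05d}",
                        disease_name=f"background disorder {i}",
                        inheritance=Inheritance.AD,
                        registration=Registration.OMIM_REGISTERED,
                        hpo_profile=profile,
                        entry_date=date,
                    )
                    entries[e.key] = e
                for _ in range(int(rng.poisson(assertion_daily))):
                    i = next(bg_assert)
                    self.background_assertions += 1
                    a = VariantAssertion(
                        variant_key=f"FILLER{i % 1000:05d}|NM_700000.1|c.{i + 1}A>G",
                        asserted_class=AssertedClass.P if i % 2 else AssertedClass.LP,
                        source="synthetic literature",
                        assertion_date=date,
                    )
                    assertions[a.variant_key] = a
            yield Snapshot(
                snapshot_date=date,
                entries=dict(entries),
                assertions=dict(assertions),
                frequencies=dict(cohort.frequencies),
            )


def generate_kb_timeline(
    config: SimulationConfig, cohort: SyntheticCohort
) -> KBTimeline:
    return KBTimeline(config, cohort)


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    n_diagnosable: int
    n_recovered: int
    false_early: int
    anticipations: int
    diagnosed_at_initial: int
    delays_days: dict[str, int] = field(default_factory=dict)
    events: list[ReclassificationEvent] = field(default_factory=list)
    reports: list = field(default_factory=list)
    wave_delays: dict[int, list[int]] = field(default_factory=dict)

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_diagnosable if self.n_diagnosable else 1.0


def replay(
    config: SimulationConfig,
    run_config: RunConfig | None = None,
) -> tuple[SyntheticCohort, ReanalysisEngine, RecoveryReport]:
    """End-to-end run: enrollment triage plus the daily loop, scored
    against the planted ground truth."""
    cohort = generate_cohort(config)
    run_config = run_config or RunConfig(seed=config.seed)
    engine = ReanalysisEngine(
        cases=[],
        ontology=cohort.ontology,
        config=run_config,
        auto_confirm=True,
    )
    by_enrollment: dict[dt.date, list[PatientCase]] = {}
    for case in cohort.cases:
        by_enrollment.setdefault(case.enrollment_date, []).append(case)

    prev: Snapshot | None = None
    for snapshot in generate_kb_timeline(config, cohort):
        date = snapshot.snapshot_date
        if prev is not None:
            delta = diff_snapshots(prev, snapshot, run_config)
            engine.daily_run(delta, snapshot, date)
        for case in by_enrollment.get(date, ()):
            engine.cases.append(case)
            engine.by_patient[case.patient_id] = case
            # classify at enrollment so the first report sees current tiers
            for cv in case.variants:
                view = engine._best_entry_view(case, cv, snapshot)
                if view is not None:
                    from .acmg import VariantClassification

                    _, tier, assignments, _ = view
                    cv.classification = VariantClassification(
                        tier, assignments, date
                    )
            report = triage_first(engine, case, snapshot, date)
        prev = snapshot

    return cohort, engine, _score(cohort, engine, config)


def triage_first(
    engine: ReanalysisEngine, case: PatientCase, snapshot: Snapshot, date: dt.date
):
    from .triage import triage_case

    report = triage_case(case, snapshot, engine.ontology, engine.config, date)
    case.report_history.append(report)
    return report


def _score(
    cohort: SyntheticCohort, engine: ReanalysisEngine, config: SimulationConfig
) -> RecoveryReport:
    wave_of: dict[str, int] = {}
    for i, case in enumerate(cohort.cases):
        wave_of[case.patient_id] = i % len(config.enrollment_waves)
    report = RecoveryReport(
        n_diagnosable=0, n_recovered=0, false_early=0, anticipations=0,
        diagnosed_at_initial=0,
    )
    all_reports = []
    for case in engine.cases:
        all_reports.extend(case.report_history)
    report.reports = all_reports
    report.events = list(engine.events)
    for pid, truth in cohort.ground_truth.items():
        if not truth.diagnosable:
            continue
        case = engine.by_patient.get(pid)
        if case is None:
            continue
        report.n_diagnosable += 1
        positive_dates = [
            r.report_date
            for r in case.report_history
            if r.category is ReportCategory.POSITIVE and r.report_date
        ]
        if not positive_dates:
            continue
        diagnosed = min(positive_dates)
        expected = case.enrollment_date
        if truth.discovery_date is not None:
            expected = max(expected, truth.discovery_date)
        if diagnosed < expected:
            report.false_early += 1
            if truth.discovery_date and diagnosed < truth.discovery_date:
                report.anticipations += 1
            continue
        report.n_recovered += 1
        first = case.report_history[0].report_date
        delay = (diagnosed - first).days
        report.delays_days[pid] = delay
        report.wave_delays.setdefault(wave_of[pid], []).append(delay)
        if delay == 0:
            report.diagnosed_at_initial += 1
    return report
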