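import datetime as dt

import pytest

from retriage.acmg import Tier
from retriage.config import DateOrderingError, RetriageError, RunConfig
from retriage.knowledge_base import (
    AssertedClass,
    Snapshot,
    VariantAssertion,
    diff_snapshots,
)
from retriage.reanalysis import (
    EventTrigger,
    ReanalysisEngine,
    ReviewDecision,
    cohort_metrics,
    eligible_cases,
)
from retriage.triage import (
    ClassifiedVariant,
    PatientCase,
    Report,
    ReportCategory,
)
from retriage.variant_model import AlleleOrigin, Variant, Zygosity

from .conftest import make_entry

CFG = RunConfig(assume_phenotype_fit=True, pm2_strength="moderate")


def splice_case(pid="345", gene="DLG4", hgvs="c.1608-2A > G"):
    v = Variant(pid, gene, "NM_001365.4", hgvs, Zygosity.HETEROZYGOUS,
                AlleleOrigin.UNKNOWN)
    return PatientCase(patient_id=pid, variants=[ClassifiedVariant(v)])


class TestEligibility:
    def _report(self, category):
        return Report(patient_id="x", category=category)

    def test_positive_excluded_others_included(self):
        cases = [PatientCase(str(i)) for i in range(3)]
        pairs = list(zip(cases, [
            self._report(ReportCategory.POSITIVE),
            self._report(ReportCategory.INCONCLUSIVE),
            self._report(ReportCategory.NEGATIVE),
        ]))
        assert eligible_cases(pairs) == cases[1:]

    def test_matches_bruteforce_filter(self):
        import random

        rng = random.Random(11)
        cases = [PatientCase(str(i)) for i in range(40)]
        pairs = [
            (c, self._report(rng.choice(list(ReportCategory)))) for c in cases
        ]
        brute = [c for c, r in pairs if r.category.value != "positive"]
        assert eligible_cases(pairs) == brute


class TestDailyRun:
    def _scenario(self):
        case = splice_case()
        engine = ReanalysisEngine([case], None, CFG, auto_confirm=True)
        s0 = Snapshot.build(dt.date(2019, 11, 15))
        engine.triage_all(s0)
        entry = make_entry(
            gene="DLG4", disease_id="618793", entry_date=dt.date(2020, 2, 26),
            name="Intellectual developmental disorder 62",
        )
        s1 = Snapshot.build(dt.date(2020, 2, 26), entries=[entry])
        return case, engine, s0, s1

    def test_new_entry_flips_negative_case_to_positive(self):
        case, engine, s0, s1 = self._scenario()
        assert case.latest_report.category is ReportCategory.NEGATIVE
        events = engine.daily_run(diff_snapshots(s0, s1, CFG), s1)
        assert len(events) == 1
        ev = events[0]
        assert ev.trigger is EventTrigger.NEW_GENE_DISEASE
        assert ev.old_tier is None and ev.new_tier is Tier.LP
        assert case.latest_report.category is ReportCategory.POSITIVE

    def test_interval_about_three_months(self):
        case, engine, s0, s1 = self._scenario()
        engine.daily_run(diff_snapshots(s0, s1, CFG), s1)
        m = cohort_metrics(engine.events, case.report_history)
        assert len(m.intervals_years) == 1
        assert m.intervals_years[0] == pytest.approx(103 / 365.25)

    def test_empty_delta_no_events(self):
        case, engine, s0, _ = self._scenario()
        assert engine.daily_run(diff_snapshots(s0, s0, CFG), s0) == []

    def test_idempotent_rerun(self):
        case, engine, s0, s1 = self._scenario()
        delta = diff_snapshots(s0, s1, CFG)
        assert len(engine.daily_run(delta, s1)) == 1
        assert engine.daily_run(delta, s1) == []

    def test_positive_case_never_reenters_queue(self):
        case, engine, s0, s1 = self._scenario()
        engine.daily_run(diff_snapshots(s0, s1, CFG), s1)
        pairs = [(case, case.latest_report)]
        assert eligible_cases(pairs) == []

    def test_snapshot_delta_date_mismatch(self):
        case, engine, s0, s1 = self._scenario()
        delta = diff_snapshots(s0, s1, CFG)
        with pytest.raises(DateOrderingError):
            engine.daily_run(delta, s0)

    def test_scoped_equals_full_scan(self):
        case_a, engine, s0, s1 = self._scenario()
        scoped = engine.daily_run(diff_snapshots(s0, s1, CFG), s1)
        case_b = splice_case()
        engine_b = ReanalysisEngine([case_b], None, CFG, auto_confirm=True)
        engine_b.triage_all(s0)
        full = engine_b.daily_run(diff_snapshots(s0, s1, CFG), s1, full_scan=True)
        assert [(e.variant_key, e.new_tier) for e in scoped] == [
            (e.variant_key, e.new_tier) for e in full
        ]


class TestLedger:
    def _emit_one(self):
        case = splice_case("X", "GENEA", "c.100del")
        engine = ReanalysisEngine([case], None, CFG, auto_confirm=False)
        s0 = Snapshot.build(dt.date(2020, 1, 1))
        engine.triage_all(s0)
        entry = make_entry(gene="GENEA", entry_date=dt.date(2020, 1, 2))
        s1 = Snapshot.build(dt.date(2020, 1, 2), entries=[entry])
        events = engine.daily_run(diff_snapshots(s0, s1, CFG), s1)
        assert len(events) == 1
        return case, engine, entry, s1, events[0]

    def test_excluded_variant_suppressed_while_evidence_unchanged(self):
        case, engine, entry, s1, ev = self._emit_one()
        engine.record_review(ev, ReviewDecision.EXCLUDED, s1)
        s0 = Snapshot.build(dt.date(2020, 1, 1))
        assert engine.daily_run(diff_snapshots(s0, s1, CFG), s1, full_scan=True) == []

    def test_excluded_variant_resurfaces_on_fingerprint_change(self):
        case, engine, entry, s1, ev = self._emit_one()
        engine.record_review(ev, ReviewDecision.EXCLUDED, s1)
        assertion = VariantAssertion(
            ev.variant_key, AssertedClass.P, source="new paper",
            assertion_date=dt.date(2020, 1, 3),
        )
        s2 = Snapshot.build(dt.date(2020, 1, 3), entries=[entry],
                            assertions=[assertion])
        events = engine.daily_run(diff_snapshots(s1, s2, CFG), s2)
        assert [e.trigger for e in events] == [EventTrigger.ASSERTION_UPDATE]

    def test_confirm_updates_report_and_queue(self):
        case, engine, entry, s1, ev = self._emit_one()
        assert case.latest_report.category is ReportCategory.NEGATIVE
        engine.record_review(ev, ReviewDecision.CONFIRMED, s1)
        assert case.latest_report.category is ReportCategory.POSITIVE
        assert eligible_cases([(case, case.latest_report)]) == []

    def test_decision_for_unknown_event_rejected(self):
        case, engine, entry, s1, ev = self._emit_one()
        from retriage.reanalysis import ReclassificationEvent

        phantom = ReclassificationEvent(
            "nobody", "G|T|c.1A>G", None, Tier.LP, None,
            EventTrigger.ASSERTION_UPDATE, dt.date(2020, 1, 2),
        )
        with pytest.raises(RetriageError):
            engine.record_review(phantom, ReviewDecision.EXCLUDED, s1)

    def test_ledger_json_roundtrip(self, tmp_path):
        case, engine, entry, s1, ev = self._emit_one()
        engine.record_review(ev, ReviewDecision.EXCLUDED, s1)
        path = tmp_path / "ledger.json"
        engine.ledger.to_json(path)
        from retriage.reanalysis import ReviewLedger

        back = ReviewLedger.from_json(path)
        assert back.entries == engine.ledger.entries


class TestPhenotypeUpdate:
    ROOT, A, B, A1, A2 = (
        "HP:0000001", "HP:0000002", "HP:0000003", "HP:0000004", "HP:0000005",
    )

    def _vus_case(self, toy_ontology):
        # missense-like substitution without protein annotation: classifies
        # VUS under any entry; flagging then hinges on the similarity score
        v = Variant("P1", "GENEA", "NM_1.1", "c.100C>T", Zygosity.HETEROZYGOUS)
        case = PatientCase("P1", hpo_terms=frozenset({self.B}),
                           variants=[ClassifiedVariant(v)])
        cfg = RunConfig(pm2_strength="moderate")
        engine = ReanalysisEngine([case], toy_ontology, cfg, auto_confirm=True)
        entry = make_entry(gene="GENEA", profile=(self.A1, self.A2),
                           entry_date=dt.date(2020, 1, 1))
        snap = Snapshot.build(dt.date(2020, 1, 1), entries=[entry])
        engine.triage_all(snap)
        return case, engine, snap

    def test_added_terms_crossing_threshold_emit_event(self, toy_ontology):
        case, engine, snap = self._vus_case(toy_ontology)
        assert case.latest_report.category is ReportCategory.NEGATIVE
        events = engine.phenotype_update(
            case, {self.A1, self.A2}, snap, dt.date(2020, 2, 1)
        )
        assert [e.trigger for e in events] == [EventTrigger.PHENOTYPE_UPDATE]
        assert events[0].new_tier is Tier.VUS
        assert events[0].similarity_score >= 5.0

    def test_unknown_terms_only_no_change(self, toy_ontology):
        case, engine, snap = self._vus_case(toy_ontology)
        assert engine.phenotype_update(
            case, {"HP:9999999"}, snap, dt.date(2020, 2, 1)
        ) == []
        assert case.hpo_terms == frozenset({self.B})

    def test_positive_case_no_events(self, toy_ontology):
        case, engine, snap = self._vus_case(toy_ontology)
        case.report_history.append(
            Report(patient_id="P1", category=ReportCategory.POSITIVE,
                   report_date=dt.date(2020, 1, 15))
        )
        assert engine.phenotype_update(
            case, {self.A1}, snap, dt.date(2020, 2, 1)
        ) == []


class TestMetrics:
    def test_single_interval_arithmetic(self):
        from retriage.reanalysis import ReclassificationEvent

        first = Report("p", ReportCategory.NEGATIVE,
                       report_date=dt.date(2020, 1, 1))
        positive = Report("p", ReportCategory.POSITIVE,
                          report_date=dt.date(2020, 3, 31))
        ev = ReclassificationEvent(
            "p", "G|T|c.1A>G", None, Tier.LP, None,
            EventTrigger.NEW_GENE_DISEASE, dt.date(2020, 3, 31),
        )
        m = cohort_metrics([ev], [first, positive])
        assert m.intervals_years == [pytest.approx(90 / 365.25)]
        assert m.daily_variant_counts == {dt.date(2020, 3, 31): 1}
        assert m.variants_per_day_mean == 1.0

    def test_event_before_first_report_is_data_error(self):
        from retriage.reanalysis import ReclassificationEvent

        first = Report("p", ReportCategory.NEGATIVE,
                       report_date=dt.date(2020, 6, 1))
        ev = ReclassificationEvent(
            "p", "G|T|c.1A>G", None, Tier.LP, None,
            EventTrigger.NEW_GENE_DISEASE, dt.date(2020, 1, 1),
        )
        with pytest.raises(RetriageError):
            cohort_metrics([ev], [first])

    def test_cumulative_curve_nondecreasing(self):
        reports = [
            Report("a", ReportCategory.POSITIVE, report_date=dt.date(2020, 1, 5)),
            Report("b", ReportCategory.POSITIVE, report_date=dt.date(2020, 1, 2)),
            Report("c", ReportCategory.NEGATIVE, report_date=dt.date(2020, 1, 1)),
        ]
        m = cohort_metrics([], reports)
        counts = [n for _, n in m.cumulative_diagnosed]
        assert counts == sorted(counts) == [1, 2]
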