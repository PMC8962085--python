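import itertools

import pytest
from hypothesis import given, strategies as st

from retriage.acmg import (
    CriterionAssignment,
    EvidenceFacts,
    Strength,
    Tier,
    TIER_ORDER,
    classify,
    combine_criteria,
    count_moderate_pathogenic,
    evaluate_criteria,
)
from retriage.config import EvidenceConflictError, RunConfig
from retriage.knowledge_base import (
    AssertedClass,
    Inheritance,
    VariantAssertion,
)
from retriage.variant_model import AlleleOrigin, Variant, Zygosity

from .conftest import make_entry
from .oracles import combine_oracle

# distinct codes per strength bucket so multisets up to 3 can be formed
_PATH_CODES = {
    "vs": ("PVS1", "PS1", "PS2", "PM5"),  # any pathogenic code may be modulated
    "s": ("PS3", "PS4", "PM1", "PP4"),
    "m": ("PM2", "PM3", "PM4", "PM6"),
    "p": ("PP1", "PP2", "PP3", "PM1"),
}
_BENIGN_CODES = {
    "bs": ("BS1", "BS2", "BS3", "BS4"),
    "bp": ("BP1", "BP2", "BP3", "BP5"),
}
_STRENGTH = {
    "vs": Strength.VERY_STRONG,
    "s": Strength.STRONG,
    "m": Strength.MODERATE,
    "p": Strength.SUPPORTING,
    "bs": Strength.STRONG,
    "bp": Strength.SUPPORTING,
}


def _assignments(vs, s, m, p, ba, bs, bp):
    out = []
    for bucket, n in (("vs", vs), ("s", s), ("m", m), ("p", p)):
        out += [
            CriterionAssignment(_PATH_CODES[bucket][i], _STRENGTH[bucket])
            for i in range(n)
        ]
    if ba:
        out.append(CriterionAssignment("BA1", Strength.STAND_ALONE))
    for bucket, n in (("bs", bs), ("bp", bp)):
        out += [
            CriterionAssignment(_BENIGN_CODES[bucket][i], _STRENGTH[bucket])
            for i in range(n)
        ]
    return tuple(out)


ALL_MULTISETS = list(
    itertools.product(range(4), range(4), range(4), range(4), range(2), range(4), range(4))
)


def test_combining_agrees_with_bruteforce_enumeration():
    """Exhaustive agreement with the independent rule-pattern evaluator over
    every criterion multiset with <= 3 per strength level (~8k cases)."""
    for vs, s, m, p, ba, bs, bp in ALL_MULTISETS:
        got = combine_criteria(_assignments(vs, s, m, p, ba, bs, bp))
        assert got.value == combine_oracle(vs, s, m, p, ba, bs, bp), (
            vs, s, m, p, ba, bs, bp,
        )


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((0, 0, 0, 0, 0, 0, 0), Tier.VUS),
        ((1, 1, 0, 1, 0, 0, 0), Tier.P),  # PVS1 + PS2 + PM2(supporting)
        ((1, 0, 1, 0, 0, 0, 0), Tier.LP),  # PVS1 + PM2(moderate)
        ((0, 0, 0, 0, 1, 0, 0), Tier.B),  # BA1
        ((0, 1, 0, 0, 0, 1, 0), Tier.VUS),  # conflicting strong evidence
        ((0, 0, 0, 0, 0, 1, 1), Tier.LB),
    ],
)
def test_worked_combinations(counts, expected):
    assert combine_criteria(_assignments(*counts)) is expected


_IDX = {t: i for i, t in enumerate(TIER_ORDER)}


@given(
    st.tuples(
        st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3),
        st.integers(0, 1), st.integers(0, 3), st.integers(0, 3),
    ),
    st.sampled_from(["vs", "s", "m", "p"]),
)
def test_adding_pathogenic_never_moves_toward_benign(counts, bucket):
    vs, s, m, p, ba, bs, bp = counts
    before = combine_oracle(vs, s, m, p, ba, bs, bp)
    bumped = dict(zip("vs s m p".split(), (vs, s, m, p)))
    bumped[bucket] += 1
    after = combine_criteria(
        _assignments(bumped["vs"], bumped["s"], bumped["m"], bumped["p"], ba, bs, bp)
    )
    assert _IDX[after] >= _IDX[Tier(before)]


@given(
    st.tuples(
        st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3),
        st.integers(0, 1), st.integers(0, 3), st.integers(0, 3),
    ),
    st.sampled_from(["bs", "bp"]),
)
def test_adding_benign_never_moves_toward_pathogenic(counts, bucket):
    vs, s, m, p, ba, bs, bp = counts
    before = combine_oracle(vs, s, m, p, ba, bs, bp)
    bumped = {"bs": bs, "bp": bp}
    bumped[bucket] += 1
    after = combine_criteria(
        _assignments(vs, s, m, p, ba, bumped["bs"], bumped["bp"])
    )
    assert _IDX[after] <= _IDX[Tier(before)]


# ---------------------------------------------------------------------------
# evaluate_criteria
# ---------------------------------------------------------------------------


def _variant(hgvs="c.1226_1229del", origin=AlleleOrigin.UNKNOWN, hgvs_p=None):
    return Variant("90", "MSL3", "NM_078629.3", hgvs, Zygosity.HETEROZYGOUS, origin, hgvs_p)


class TestEvaluate:
    def test_de_novo_lof_frameshift(self):
        facts = EvidenceFacts(
            population_absent=True, lof_mechanism=True, de_novo=True
        )
        got = evaluate_criteria(
            _variant(origin=AlleleOrigin.ASSUMED_DE_NOVO), facts, make_entry()
        )
        by_code = {a.code: a.applied_strength for a in got}
        assert by_code == {
            "PVS1": Strength.VERY_STRONG,
            "PS2": Strength.STRONG,
            "PM2": Strength.SUPPORTING,
        }
        assert combine_criteria(got) is Tier.P

    def test_common_variant_is_ba1_only(self):
        got = evaluate_criteria(
            _variant(), EvidenceFacts(population_af=0.12), make_entry()
        )
        assert [a.code for a in got] == ["BA1"]
        assert combine_criteria(got) is Tier.B

    def test_missense_with_no_facts_is_empty(self):
        got = evaluate_criteria(
            _variant("c.560C>T"), EvidenceFacts(), make_entry(lof=False)
        )
        assert got == []

    def test_nmd_escape_downgrades_pvs1(self):
        facts = EvidenceFacts(lof_mechanism=True, nmd_predicted=False)
        got = evaluate_criteria(_variant(), facts, make_entry())
        assert {a.code: a.applied_strength for a in got} == {
            "PVS1": Strength.MODERATE
        }

    def test_matching_assertion_gives_ps1(self):
        assertion = VariantAssertion("MSL3|NM_078629.3|c.1226_1229del", AssertedClass.P)
        facts = EvidenceFacts(matching_assertion=assertion)
        codes = {a.code for a in evaluate_criteria(_variant(), facts, make_entry(lof=False))}
        assert codes == {"PS1"}

    def test_pm3_requires_recessive_entry(self):
        facts = EvidenceFacts(in_trans_with_plp=True)
        ar = {a.code for a in evaluate_criteria(
            _variant(), facts, make_entry(inheritance=Inheritance.AR, lof=False)
        )}
        ad = {a.code for a in evaluate_criteria(
            _variant(), facts, make_entry(inheritance=Inheritance.AD, lof=False)
        )}
        assert "PM3" in ar and "PM3" not in ad

    def test_pm2_threshold_depends_on_inheritance(self):
        facts = EvidenceFacts(population_af=5e-5)
        ar = {a.code for a in evaluate_criteria(
            _variant(), facts, make_entry(inheritance=Inheritance.AR, lof=False)
        )}
        ad = {a.code for a in evaluate_criteria(
            _variant(), facts, make_entry(inheritance=Inheritance.AD, lof=False)
        )}
        assert "PM2" in ar and "PM2" not in ad  # 5e-5 < 1e-4 but > 1e-5

    def test_bs1_uses_disease_specific_cutoff(self):
        config = RunConfig(bs1_af={"600001": 1e-4})
        facts = EvidenceFacts(population_af=5e-4)
        codes = {a.code for a in evaluate_criteria(
            _variant(), facts, make_entry(lof=False), config
        )}
        assert "BS1" in codes

    def test_conflicting_origin_raises(self):
        facts = EvidenceFacts(de_novo=True)
        with pytest.raises(EvidenceConflictError):
            evaluate_criteria(
                _variant(origin=AlleleOrigin.INHERITED_UNAFFECTED_PARENT),
                facts,
                make_entry(),
            )

    def test_classification_audit_roundtrip(self):
        facts = EvidenceFacts(
            population_absent=True, lof_mechanism=True, de_novo=True
        )
        classification = classify(
            _variant(origin=AlleleOrigin.ASSUMED_DE_NOVO), facts, make_entry()
        )
        assert classification.recomputed_tier() is classification.tier


class TestModerateCount:
    @pytest.mark.parametrize(
        "counts, expected",
        [((0, 0, 2, 0, 0, 0, 0), 2), ((0, 0, 0, 1, 0, 0, 0), 0), ((1, 2, 3, 1, 0, 2, 1), 3)],
    )
    def test_counts(self, counts, expected):
        assert count_moderate_pathogenic(_assignments(*counts)) == expected

    @given(
        st.tuples(
            st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3),
            st.integers(0, 1), st.integers(0, 3), st.integers(0, 3),
        )
    )
    def test_equals_bruteforce_filter(self, counts):
        assignments = _assignments(*counts)
        brute = len(
            [
                a
                for a in assignments
                if a.applied_strength is Strength.MODERATE
                and a.code[0] == "P"
            ]
        )
        assert count_moderate_pathogenic(assignments) == brute


def test_ba1_strength_is_enforced():
    with pytest.raises(ValueError):
        CriterionAssignment("BA1", Strength.STRONG)
    with pytest.raises(ValueError):
        CriterionAssignment("PM2", Strength.STAND_ALONE)
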