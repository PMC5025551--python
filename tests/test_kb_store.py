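from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from rtdx.core_model import (
    InstantiationAssertion,
    NegativeAssertion,
    Particular,
    RelationAssertion,
    TEMPORAL_RELATIONS,
    TemporalConstraint,
    TemporalRegion,
    Universal,
    Verdict,
)
from rtdx.errors import DeclarationError, InconsistencyError
from rtdx.kb_store import KnowledgeBase

from _oracles import _sat, oracle_entails
from conftest import shuffled_rebuild

RELS = sorted(TEMPORAL_RELATIONS)


def small_kb() -> KnowledgeBase:
    kb = KnowledgeBase()
    for t in ("t1", "t2"):
        kb.add(TemporalRegion(t))
    kb.add(Particular("IUI-1", "Mr. Adam Jones", "t1"))
    kb.add(Particular("IUI-2", "his disease", "t2"))
    kb.add(Universal("UUI-1", "type 2 diabetes mellitus"))
    return kb


class TestAdd:
    def test_added_assertion_queryable(self):
        kb = small_kb()
        a = RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t2")
        kb.add(a)
        assert kb.query("IUI-2", "inheres_in", "IUI-1", "t2") == frozenset({a})

    def test_add_twice_idempotent(self):
        kb1, kb2 = small_kb(), small_kb()
        a = RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t2")
        kb1.add(a)
        kb2.add(a)
        kb2.add(a)
        assert kb1.relations == kb2.relations

    def test_undeclared_referent_rejected(self):
        kb = small_kb()
        with pytest.raises(DeclarationError) as exc:
            kb.add(RelationAssertion("IUI-99", "part_of", "IUI-1", "t1"))
        assert "IUI-99" in str(exc.value)


class TestQuery:
    def test_is_about_fanout_scenario1(self, scenario1):
        kb, _ = scenario1
        hits = kb.query("IUI-6", "is_about")
        assert {a.object for a in hits} == {"IUI-7", "IUI-1", "IUI-2", "UUI-1"}
        assert len(hits) == 4

    def test_no_misrepresentation_in_correct_scenario(self, scenario1):
        kb, _ = scenario1
        assert kb.query(relation="is_misrepresentation_of") == frozenset()

    def test_concretizations_of_diagnosis(self, scenario1):
        kb, _ = scenario1
        subjects = {a.subject for a in kb.query(object="IUI-8", relation="concretizes")}
        assert subjects == {"IUI-6", "IUI-10"}

    def test_result_is_set_like(self, scenario1):
        kb, _ = scenario1
        assert isinstance(kb.query(), frozenset)

    def test_invariant_under_insertion_order(self, scenario1):
        kb, _ = scenario1
        rebuilt = shuffled_rebuild(kb, seed=7)
        assert rebuilt.query() == kb.query()
        assert rebuilt.query("IUI-6", "is_about") == kb.query("IUI-6", "is_about")


class TestEntailsTemporal:
    def test_ends_implies_during(self):
        kb = KnowledgeBase()
        for t in ("t11", "t16"):
            kb.add(TemporalRegion(t))
        kb.add(TemporalConstraint("t16", "ends", "t11"))
        assert kb.entails_temporal("t16", "during", "t11") is Verdict.HOLDS

    def test_equals_reflexive(self):
        kb = small_kb()
        for t in kb.temporal_regions:
            assert kb.entails_temporal(t, "equals", t) is Verdict.HOLDS

    def test_during_refutes_before_but_not_equals(self):
        # frozen from endpoint enumeration over a small integer timeline
        kb = KnowledgeBase()
        for t in ("t11", "t21"):
            kb.add(TemporalRegion(t))
        kb.add(TemporalConstraint("t21", "during", "t11"))
        assert kb.entails_temporal("t21", "before", "t11") is Verdict.FAILS
        assert kb.entails_temporal("t21", "equals", "t11") is Verdict.INDETERMINATE

    def test_undeclared_region(self):
        kb = small_kb()
        with pytest.raises(DeclarationError):
            kb.entails_temporal("t1", "before", "t404")

    def test_inconsistent_network_reports_cycle(self):
        kb = KnowledgeBase()
        for t in ("t1", "t2"):
            kb.add(TemporalRegion(t))
        kb.add(TemporalConstraint("t1", "before", "t2"))
        kb.add(TemporalConstraint("t2", "before", "t1"))
        with pytest.raises(InconsistencyError) as exc:
            kb.entails_temporal("t1", "during", "t2")
        assert exc.value.cycle  # lists a violating cycle

    @staticmethod
    def _random_consistent_network(rng: random.Random, n: int):
        """Constraints sampled as true statements about concrete intervals."""
        vals = {}
        for i in range(n):
            s = rng.randint(0, 10)
            vals[f"t{i}"] = (s, rng.randint(s, 11))
        cons = []
        for _ in range(rng.randint(n - 1, n + 2)):
            x, y = rng.sample(sorted(vals), 2)
            opts = [(x, r, y) for r in RELS if _sat(r, vals[x], vals[y])]
            opts += [(y, r, x) for r in RELS if _sat(r, vals[y], vals[x])]
            cons.append(TemporalConstraint(*rng.choice(opts)))
        return sorted(vals), cons

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_agreement_consistent_networks(self, seed):
        rng = random.Random(seed)
        for _ in range(30):
            n = rng.randint(2, 5)
            tids, cons = self._random_consistent_network(rng, n)
            kb = KnowledgeBase()
            for t in tids:
                kb.add(TemporalRegion(t))
            for c in cons:
                kb.add(c)
            a, b = rng.sample(tids, 2)
            q = rng.choice(RELS)
            assert kb.entails_temporal(a, q, b) == oracle_entails(tids, cons, a, q, b)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_oracle_agreement_arbitrary_small_networks(self, seed):
        # fully random (possibly inconsistent) networks, small enough for
        # the enumeration oracle to exhaust
        rng = random.Random(seed)
        n = rng.randint(2, 3)
        tids = [f"t{i}" for i in range(n)]
        cons = []
        for _ in range(rng.randint(1, n + 1)):
            x, y = rng.sample(tids, 2)
            cons.append(TemporalConstraint(x, rng.choice(RELS), y))
        kb = KnowledgeBase()
        for t in tids:
            kb.add(TemporalRegion(t))
        for c in cons:
            kb.add(c)
        a, b = rng.sample(tids, 2)
        q = rng.choice(RELS)
        try:
            impl = kb.entails_temporal(a, q, b)
        except InconsistencyError:
            impl = None
        assert impl == oracle_entails(tids, cons, a, q, b)

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_refinement(self, seed):
        # adding a constraint to a consistent network may only resolve
        # indeterminate verdicts, never flip definite ones
        rng = random.Random(seed)
        n = rng.randint(3, 5)
        tids, cons = self._random_consistent_network(rng, n)
        kb = KnowledgeBase()
        for t in tids:
            kb.add(TemporalRegion(t))
        for c in cons:
            kb.add(c)
        before = {
            (a, q, b): kb.entails_temporal(a, q, b)
            for a in tids
            for b in tids
            if a != b
            for q in RELS
        }
        _, extra = self._random_consistent_network(rng, n)
        kb2 = kb.copy()
        try:
            for c in extra[:2]:
                kb2.add(c)
            after = {k: kb2.entails_temporal(*k) for k in before}
        except InconsistencyError:
            return  # the combined network happened to be inconsistent; nothing to compare
        for key, v_before in before.items():
            if v_before is not Verdict.INDETERMINATE:
                assert after[key] is v_before, key


class TestCheckConsistency:
    def test_scenario1_clean(self, scenario1):
        kb, _ = scenario1
        assert kb.check_consistency() == []

    def test_assertion_before_existence(self):
        kb = small_kb()
        kb.add(TemporalRegion("t0"))
        kb.add(TemporalConstraint("t0", "before", "t1"))
        # diagnosis-shaped assertion anchored before the organism existed
        kb.add(RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t0"))
        violations = kb.check_consistency()
        assert any("outside the existence interval" in v for v in violations)

    def test_positive_negative_clash_same_region(self):
        kb = small_kb()
        kb.add(InstantiationAssertion("IUI-2", "UUI-1", "t2"))
        kb.add(RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t2"))
        kb.add(NegativeAssertion("IUI-1", "inheres_in", "UUI-1", "t2"))  # no clash: wrong subject
        kb.add(NegativeAssertion("IUI-2", "inheres_in", "UUI-1", "t2"))  # IUI-1 is not an instance of UUI-1
        assert kb.check_consistency() == []
        # now negate the very relation that is positively asserted
        kb2 = small_kb()
        kb2.add(InstantiationAssertion("IUI-1", "UUI-1", "t1"))
        kb2.add(RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t2"))
        kb2.add(NegativeAssertion("IUI-2", "inheres_in", "UUI-1", "t2"))
        violations = kb2.check_consistency()
        assert len([v for v in violations if "clash" in v]) == 1

    def test_clash_requires_entailed_overlap(self):
        # distinct, unconstrained regions: overlap is possible but not
        # entailed, so no clash is reported
        kb = small_kb()
        kb.add(TemporalRegion("t9"))
        kb.add(InstantiationAssertion("IUI-1", "UUI-1", "t1"))
        kb.add(RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t2"))
        kb.add(NegativeAssertion("IUI-2", "inheres_in", "UUI-1", "t9"))
        assert kb.check_consistency() == []


class TestRoundTripInvariance:
    def test_query_stable_across_serialization(self, scenario3):
        from rtdx.io_cli import dumps_rt, loads_rt

        kb, _ = scenario3
        kb2 = loads_rt(dumps_rt(kb))
        assert kb2.query() == kb.query()
        assert kb2.temporal_constraints == kb.temporal_constraints
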