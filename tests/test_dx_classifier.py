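from __future__ import annotations

import logging
from dataclasses import replace

import pytest

from rtdx.aboutness import evaluate_compound
from rtdx.core_model import (
    AssertionContent,
    Category,
    FailureMode,
    Particular,
    TemporalConstraint,
    TemporalRegion,
    Universal,
    Verdict,
)
from rtdx.dx_classifier import (
    check_precision,
    classify_assertion,
    classify_failure_modes,
    classify_target,
    is_diagnostic_process,
)
from rtdx.scenarios import PerturbationSpec, build_scenario, perturb, random_scenario

from conftest import shuffled_rebuild


class TestIsDiagnosticProcess:
    def test_physician_process_holds(self, scenario1):
        kb, _ = scenario1
        assert is_diagnostic_process(kb.processes["IUI-11"], kb) is Verdict.HOLDS

    def test_seer_reasoning_fails(self, scenario4):
        kb, _ = scenario4
        assert is_diagnostic_process(kb.processes["IUI-71"], kb) is Verdict.FAILS

    def test_expert_system_holds(self, scenario6):
        kb, _ = scenario6
        process = kb.processes["IUI-106"]
        assert process.agent_is_human is False
        assert is_diagnostic_process(process, kb) is Verdict.HOLDS


class TestClassifyFailureModes:
    def test_scenario3_wrong_existing_type(self, scenario3):
        kb, _ = scenario3
        modes, fails_first = classify_failure_modes(kb.ices["IUI-48"].content, kb)
        assert modes == {FailureMode.NONINST_TYPE_EXISTS}
        assert fails_first == "compound"

    def test_twin_non_inherence(self, scenario1):
        kb = scenario1[0].copy()
        kb.add(TemporalRegion("t95"))
        kb.add(Particular("IUI-95", "the patient's twin", "t95"))
        content = replace(kb.ices["IUI-8"].content, asserted_organism="IUI-95")
        modes, fails_first = classify_failure_modes(content, kb)
        assert modes == {FailureMode.NON_INHERENCE}
        assert fails_first == "compound"

    def test_spacetime_misplacement(self, scenario1):
        kb = scenario1[0].copy()
        kb.add(TemporalRegion("t96"))
        kb.add(TemporalConstraint("t96", "before", "t2"))  # five years before onset
        content = replace(kb.ices["IUI-8"].content, asserted_anchor="t96")
        modes, fails_first = classify_failure_modes(content, kb)
        assert modes == {FailureMode.SPACETIME_MISPLACEMENT}
        assert fails_first == "compound"

    def test_correct_content_no_modes(self, scenario1):
        kb, _ = scenario1
        modes, fails_first = classify_failure_modes(kb.ices["IUI-8"].content, kb)
        assert modes == frozenset()
        assert fails_first == "none"

    def test_single_fault_perturbations_recover_each_mode(self, scenario1):
        kb, _ = scenario1
        for mode in FailureMode:
            perturbed, content = perturb(kb, PerturbationSpec(mode))
            modes, fails_first = classify_failure_modes(content, perturbed)
            assert modes == {mode}
            expected_first = (
                "reference"
                if mode
                in {
                    FailureMode.NONINST_TYPE_NONEXISTENT,
                    FailureMode.DISEASE_NONEXISTENT,
                    FailureMode.ORGANISM_NONEXISTENT,
                }
                else "compound"
            )
            assert fails_first == expected_first

    def test_single_edit_enumeration_partitions_into_modes(self, scenario1):
        """Every single-field edit of the correct content yields exactly the
        mode its fault class predicts — no residue, no overlap."""
        kb = scenario1[0].copy()
        kb.add(Universal("UUI-2", "type 1 diabetes mellitus"))
        kb.add(Universal("UUI-66", "dropsy", exists_flag=False))
        kb.add(TemporalRegion("t95"))
        kb.add(Particular("IUI-95", "the patient's twin", "t95"))
        kb.add(TemporalRegion("t96"))
        kb.add(TemporalConstraint("t96", "before", "t2"))
        kb.add(TemporalRegion("t97"))
        kb.add(TemporalConstraint("t97", "during", "t2"))
        base = kb.ices["IUI-8"].content

        edits = {
            ("asserted_type", "UUI-2"): {FailureMode.NONINST_TYPE_EXISTS},
            ("asserted_type", "UUI-66"): {FailureMode.NONINST_TYPE_NONEXISTENT},
            ("asserted_disease", "IUI-666"): {FailureMode.DISEASE_NONEXISTENT},
            ("asserted_organism", "IUI-777"): {FailureMode.ORGANISM_NONEXISTENT},
            ("asserted_organism", "IUI-95"): {FailureMode.NON_INHERENCE},
            ("asserted_anchor", "t96"): {FailureMode.SPACETIME_MISPLACEMENT},
            # harmless edits: anchored to an entailed-overlapping region
            ("asserted_anchor", "t97"): set(),
            ("asserted_anchor", "t2"): set(),
        }
        seen: set[FailureMode] = set()
        for (field, value), expected in edits.items():
            modes, _ = classify_failure_modes(replace(base, **{field: value}), kb)
            assert modes == frozenset(expected), (field, value)
            seen |= expected
        assert seen == set(FailureMode)  # all six modes, nothing else


class TestClassifyAssertion:
    def test_battery(self, scenario1, scenario2, scenario3, scenario4, scenario5, scenario6):
        expected = [
            (scenario1, Category.CORRECT_DIAGNOSIS),
            (scenario2, Category.CORRECT_DIAGNOSIS),
            (scenario3, Category.MISDIAGNOSIS),
            (scenario4, Category.LUCKY_GUESS),
            (scenario5, Category.JUSTIFIED_CONCLUSION),
            (scenario6, Category.CORRECT_DIAGNOSIS),
        ]
        for (kb, target), category in expected:
            assert classify_target(kb, target).category is category

    def test_scenario3_modes(self, scenario3):
        kb, target = scenario3
        result = classify_target(kb, target)
        assert result.category is Category.MISDIAGNOSIS
        assert result.failure_modes == {FailureMode.NONINST_TYPE_EXISTS}
        assert result.fails_first == "compound"

    def test_copy_variant_is_hearsay(self, scenario5_copy):
        kb, target = scenario5_copy
        result = classify_target(kb, target)
        assert result.category is Category.HEARSAY_COPY
        assert result.failure_modes == frozenset()

    def test_coin_flip_physician_is_lucky_guess(self, scenario1):
        # a physician concluding without aggregate or picture input
        from rtdx.core_model import ICERecord, ProcessRecord, RepresentationRecord

        kb = scenario1[0].copy()
        kb.add(TemporalRegion("t98"))
        kb.add(TemporalConstraint("t98", "during", "t2"))
        kb.add(
            RepresentationRecord("IUI-200", "cognitive", "IUI-5", "IUI-201", "t98")
        )
        kb.add(
            ProcessRecord(
                "IUI-202", agent="IUI-3", agent_is_human=True,
                inputs=frozenset(), outputs=frozenset({"IUI-200", "IUI-201"}), occupies="t98",
            )
        )
        kb.add(
            ICERecord(
                "IUI-201",
                content=replace(kb.ices["IUI-8"].content, asserted_anchor="t98"),
                concretizations=frozenset({"IUI-200"}),
                produced_by="IUI-202",
                first_concretized_at="t98",
            )
        )
        assert classify_target(kb, "IUI-201").category is Category.LUCKY_GUESS

    def test_all_three_nonexistence_faults_is_non_ice(self, scenario1):
        kb = scenario1[0].copy()
        kb.add(Universal("UUI-66", "spattergroit", exists_flag=False))
        ice = kb.ices["IUI-8"]
        content = replace(
            ice.content,
            asserted_organism="IUI-888",
            asserted_disease="IUI-889",
            asserted_type="UUI-66",
        )
        kb.replace_ice(replace(ice, content=content))
        result = classify_target(kb, "IUI-8")
        assert result.category is Category.NON_ICE
        assert result.failure_modes >= {
            FailureMode.ORGANISM_NONEXISTENT,
            FailureMode.DISEASE_NONEXISTENT,
            FailureMode.NONINST_TYPE_NONEXISTENT,
        }
        assert result.fails_first == "reference"

    def test_organism_nonexistent_never_misdiagnosis(self, scenario1):
        # 'James Bond has influenza': an ICE, but not a (mis)diagnosis
        kb, _ = scenario1
        perturbed, _ = perturb(kb, PerturbationSpec(FailureMode.ORGANISM_NONEXISTENT))
        result = classify_target(perturbed, "IUI-8")
        assert result.category not in (Category.MISDIAGNOSIS, Category.CORRECT_DIAGNOSIS)
        assert result.category is not Category.NON_ICE  # still about the disease and type

    def test_indeterminate_anchor_yields_indeterminate(self, scenario1):
        kb = scenario1[0].copy()
        kb.add(TemporalRegion("t99"))  # unconstrained relative to t2
        ice = kb.ices["IUI-8"]
        kb.replace_ice(replace(ice, content=replace(ice.content, asserted_anchor="t99")))
        assert classify_target(kb, "IUI-8").category is Category.INDETERMINATE

    @pytest.mark.parametrize("seed", range(15))
    def test_correct_diagnosis_biconditional(self, seed):
        # correct_diagnosis <=> diagnostic process holds AND compound holds
        kb, expected = random_scenario(seed, 14, 0.5)
        for target, _ in expected:
            if target not in kb.ices:
                continue
            ice = kb.ices[target]
            result = classify_assertion(ice, kb)
            diagnostic = (
                ice.produced_by is not None
                and is_diagnostic_process(kb.processes[ice.produced_by], kb) is Verdict.HOLDS
            )
            compound_holds = evaluate_compound(ice.content, kb).status is Verdict.HOLDS
            assert (result.category is Category.CORRECT_DIAGNOSIS) == (diagnostic and compound_holds)

    @pytest.mark.parametrize("seed", range(15))
    def test_misdiagnosis_implications(self, seed):
        from rtdx.aboutness import evaluate_reference

        kb, expected = random_scenario(seed, 14, 0.7)
        for target, _ in expected:
            if target not in kb.ices:
                continue
            result = classify_assertion(kb.ices[target], kb)
            if result.category is Category.MISDIAGNOSIS:
                content = kb.ices[target].content
                ref = evaluate_reference(content, kb)
                assert Verdict.HOLDS in ref.per_referent.values()
                assert evaluate_compound(content, kb).status is Verdict.FAILS
                assert result.failure_modes

    @pytest.mark.parametrize("seed", [3, 11])
    def test_invariant_under_insertion_order(self, seed, scenario3):
        kb, target = scenario3
        rebuilt = shuffled_rebuild(kb, seed)
        assert classify_target(rebuilt, target) == classify_target(kb, target)


class TestCheckPrecision:
    HIERARCHY = {"UUI-1": "UUI-10", "UUI-10": "UUI-11"}  # t2dm < DM < disease

    def test_root_warns(self, scenario1):
        kb, _ = scenario1
        content = replace(kb.ices["IUI-8"].content, asserted_type="UUI-11")
        assert check_precision(content, self.HIERARCHY, "UUI-11") is not None

    def test_leaf_silent(self, scenario1):
        kb, _ = scenario1
        assert check_precision(kb.ices["IUI-8"].content, self.HIERARCHY, "UUI-11") is None

    def test_configured_stratum_warns(self, scenario1):
        kb, _ = scenario1
        content = replace(kb.ices["IUI-8"].content, asserted_type="UUI-10")
        assert check_precision(content, self.HIERARCHY, "UUI-11", too_general=["UUI-10"]) is not None

    def test_empty_hierarchy_logs_notice(self, scenario1, caplog):
        kb, _ = scenario1
        with caplog.at_level(logging.INFO, logger="rtdx.dx_classifier"):
            assert check_precision(kb.ices["IUI-8"].content, {}, "UUI-11") is None
        assert any("empty type hierarchy" in r.message for r in caplog.records)
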