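"""Fixture builders for the six worked scenarios, single-fault perturbations,
and seeded synthetic knowledge bases for property testing.

All six scenarios share one patient, Mr. Adam Jones (IUI-1), his disease
(IUI-2), the type *type 2 diabetes mellitus* (UUI-1), and the configuration
of these three entities (IUI-7).  Scenario-specific particulars are numbered
in blocks; identifiers quoted from the published tuple tables are used
verbatim, while gaps in the numbering (supplementary tables are not bundled)
are filled with documented placeholder identifiers, marked ``# placeholder``
below.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .core_model import (
    AssertionContent,
    Category,
    ClinicalPictureRecord,
    FailureMode,
    ICERecord,
    InstantiationAssertion,
    KnowledgeAggregate,
    NegativeAssertion,
    Particular,
    ProcessRecord,
    RelationAssertion,
    RepresentationRecord,
    TemporalConstraint,
    TemporalRegion,
    Universal,
    make_configuration,
)
from .kb_store import KnowledgeBase
from .provenance import copy_concretization

__all__ = ["PerturbationSpec", "build_scenario", "perturb", "random_scenario"]


@dataclass(frozen=True)
class PerturbationSpec:
    """One single-fault edit to a scenario's diagnostic content."""

    mode: FailureMode
    seed: int = 0
    target: str = ""  # content field being edited; informational


def _regions(kb: KnowledgeBase, *tids: str) -> None:
    for t in tids:
        kb.add(TemporalRegion(t))


def _base_kb() -> KnowledgeBase:
    """Tuples true in every scenario: patient, disease, type, configuration."""
    kb = KnowledgeBase()
    _regions(kb, "t1", "t2", "t7")
    kb.add(Universal("UUI-1", "type 2 diabetes mellitus"))
    kb.add(Particular("IUI-1", "Mr. Adam Jones", "t1"))
    kb.add(Particular("IUI-2", "IUI-1's disease", "t2"))
    kb.add(InstantiationAssertion("IUI-2", "UUI-1", "t2"))
    kb.add(RelationAssertion("IUI-2", "inheres_in", "IUI-1", "t2"))
    kb.add(
        make_configuration(
            "IUI-1", "IUI-2", "UUI-1", "t2",
            config_id="IUI-7",
            declared=kb.declared_ids(),
        )
    )
    # the configuration's own existence period; a distinct identifier may
    # denote the same period as t2
    kb.add(TemporalConstraint("t7", "equals", "t2"))
    kb.add(TemporalConstraint("t2", "during", "t1"))
    return kb


def _physician_block(
    kb: KnowledgeBase,
    offset: int,
    doctor_label: str,
    asserted_type: str,
    aggregate_types: frozenset[str],
    extra_picture_sources: frozenset[str] = frozenset(),
    extra_process_inputs: frozenset[str] = frozenset(),
) -> str:
    """Add one physician's diagnosing-and-writing block, offset from the
    Scenario 1 numbering (doctor IUI-3, …, writing IUI-13, aggregate IUI-14).

    Returns the id of the diagnosis ICE.
    """
    i = lambda n: f"IUI-{n + offset}"
    t = lambda n: f"t{n + offset}"
    doctor, cogsys, part, cogrep = i(3), i(4), i(5), i(6)
    ice, paper, iqe = i(8), i(9), i(10)
    process, picture, writing = i(11), i(12), i(13)
    aggregate, finding = i(14), i(15)  # aggregate id real in scenario 1; finding is a placeholder

    _regions(kb, *(t(n) for n in (3, 4, 5, 6, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21)))
    kb.add(TemporalConstraint(t(16), "ends", t(11)))  # the diagnosis begins to exist as the process concludes
    kb.add(TemporalConstraint(t(15), "during", t(11)))
    kb.add(TemporalConstraint(t(21), "during", t(11)))
    kb.add(TemporalConstraint(t(16), "starts", t(8)))
    # the diagnosis asserts the disease as present while the diagnosis exists
    kb.add(TemporalConstraint(t(8), "during", "t2"))

    kb.add(Particular(doctor, doctor_label, t(3)))
    kb.add(Particular(cogsys, f"cognitive system of {doctor}", t(4)))
    kb.add(Particular(part, f"anatomical entity, part of {cogsys}", t(5)))
    kb.add(Particular(paper, "sentence as written on paper", t(9)))
    kb.add(Particular(finding, f"finding record used for {picture}", t(12)))  # placeholder

    kb.add(
        RepresentationRecord(cogrep, "cognitive", bearer=part, concretizes=ice, exists_during=t(6))
    )
    kb.add(
        RepresentationRecord(iqe, "inscription_quality", bearer=paper, concretizes=ice, exists_during=t(10))
    )
    content = AssertionContent(
        asserted_organism="IUI-1",
        asserted_disease="IUI-2",
        asserted_type=asserted_type,
        asserted_anchor=t(8),
        intended_target="IUI-7",
    )
    kb.add(
        ICERecord(
            ice,
            content=content,
            concretizations=frozenset({cogrep, iqe}),
            produced_by=process,
            first_concretized_at=t(16),
        )
    )
    kb.add(
        ClinicalPictureRecord(
            picture,
            subject="IUI-1",
            inferred_from=frozenset({finding}) | extra_picture_sources,
            exists_during=t(12),
        )
    )
    kb.add(
        KnowledgeAggregate(
            aggregate,
            disease_types=aggregate_types,
            phenotype_types=frozenset({"UUI-3"}),
            owner=doctor,
        )
    )
    kb.add(
        ProcessRecord(
            process,
            agent=doctor,
            agent_is_human=True,
            inputs=frozenset({picture, aggregate}) | extra_process_inputs,
            outputs=frozenset({cogrep, ice}),
            occupies=t(11),
        )
    )
    kb.add(
        ProcessRecord(
            writing,
            agent=doctor,
            agent_is_human=True,
            inputs=frozenset({ice, cogrep}),
            outputs=frozenset({iqe}),
            occupies=t(13),
        )
    )

    R = RelationAssertion
    kb.add(R(cogsys, "part_of", doctor, t(4)))
    kb.add(R(part, "part_of", cogsys, t(14)))
    kb.add(R(cogrep, "inheres_in", part, t(6)))
    kb.add(R(cogrep, "concretizes", ice, t(6)))
    kb.add(R(iqe, "inheres_in", paper, t(9)))
    kb.add(R(iqe, "concretizes", ice, t(10)))
    kb.add(R(iqe, "is_conformant_to", cogrep, t(10)))
    kb.add(R(doctor, "agent_in", process, t(11)))
    kb.add(R(picture, "input_into", process, t(15)))
    kb.add(R(aggregate, "input_into", process, t(21)))
    kb.add(R(cogrep, "output_of", process, t(16)))
    kb.add(R(ice, "output_of", process, t(16)))
    kb.add(R(ice, "input_into", writing, t(17)))
    kb.add(R(cogrep, "input_into", writing, t(18)))
    kb.add(R(iqe, "output_of", writing, t(19)))

    # aboutness rows: toward each referent, and toward the configuration when
    # the compound holds, or misrepresentation of it when it fails
    from .aboutness import infer_aboutness_relations  # late import; no cycle at module load

    for rep in (cogrep, iqe):
        for a in infer_aboutness_relations(kb.representations[rep], kb):
            kb.add(a)
    return ice


def _scenario_1(kb: KnowledgeBase) -> str:
    kb.add(Universal("UUI-3", "hyperglycemia (associated phenotype)"))  # placeholder
    kb.add(Universal("UUI-4", "coughing event"))
    ice = _physician_block(kb, 0, "Dr. Anne Smith", "UUI-1", frozenset({"UUI-1"}))
    # elicited during history taking: no coughing in the picture's period
    kb.add(NegativeAssertion("IUI-1", "agent_in", "UUI-4", "t12"))
    return ice


def build_scenario(n: int, variant: str = "belief") -> tuple[KnowledgeBase, str]:
    """Build scenario ``n`` (1..6); returns (KB, id of the assertion under test).

    Scenario 5 has two variants: ``belief`` (the daughter forms her own
    conclusion; a new ICE) and ``copy`` (she copies the physician's sentence
    verbatim; the target is then the copied representation).
    """
    if n not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"scenario number out of range: {n}")
    kb = _base_kb()
    if n == 1:
        target = _scenario_1(kb)
    elif n == 2:
        # Dr. Brown reads Dr. Smith's diagnosis: the scenario 1 block exists
        # too.  IUI-1, IUI-2, IUI-7 are shared; there is no IUI-21, IUI-22 or
        # IUI-27.  The prior diagnosis enters both the new clinical picture
        # (view1) and the process inputs directly (view2).
        _scenario_1(kb)
        target = _physician_block(
            kb, 20, "Dr. John Brown", "UUI-1", frozenset({"UUI-1"}),
            extra_picture_sources=frozenset({"IUI-8"}),
            extra_process_inputs=frozenset({"IUI-8"}),
        )
    elif n == 3:
        kb.add(Universal("UUI-2", "type 1 diabetes mellitus"))
        kb.add(Universal("UUI-3", "hyperglycemia (associated phenotype)"))  # placeholder
        target = _physician_block(
            kb, 40, "Dr. Jane Miller", "UUI-2", frozenset({"UUI-1", "UUI-2"})
        )
    elif n == 4:
        target = _scenario_4(kb)
    elif n == 5:
        if variant not in ("belief", "copy"):
            raise ValueError(f"unknown scenario 5 variant: {variant!r}")
        kb.add(Universal("UUI-3", "hyperglycemia (associated phenotype)"))  # placeholder
        kb.add(Universal("UUI-4", "coughing event"))
        _scenario_1(kb)
        target = _scenario_5(kb, variant)
    else:
        target = _scenario_6(kb)
    kb.metadata.update({"scenario": n, "ice_under_test": target})
    if n == 5:
        kb.metadata["variant"] = variant
    violations = kb.check_consistency()
    assert not violations, f"scenario {n} fixture inconsistent: {violations}"
    return kb, target


def _scenario_4(kb: KnowledgeBase) -> str:
    """The seer's coincidentally correct conclusion."""
    t = lambda n: f"t{n}"
    _regions(kb, "t63", "t64", "t65", "t66", "t68", "t71", "t72", "t73")
    kb.add(TemporalConstraint("t68", "during", "t2"))
    kb.add(Particular("IUI-63", "the seer", "t63"))
    kb.add(Particular("IUI-64", "cognitive system of IUI-63", "t64"))  # placeholder
    kb.add(Particular("IUI-65", "anatomical entity, part of IUI-64", "t65"))  # placeholder
    kb.add(Particular("IUI-72", "Mr. Jones' horoscope", "t72"))  # placeholder
    kb.add(Particular("IUI-73", "the position of the moon", "t73"))  # placeholder
    kb.add(
        RepresentationRecord(
            "IUI-66", "cognitive", bearer="IUI-65", concretizes="IUI-68", exists_during="t66"
        )
    )  # placeholder id
    content = AssertionContent(
        asserted_organism="IUI-1",
        asserted_disease="IUI-2",
        asserted_type="UUI-1",
        asserted_anchor="t68",
        intended_target="IUI-7",
    )
    kb.add(
        ICERecord(
            "IUI-68",
            content=content,
            concretizations=frozenset({"IUI-66"}),
            produced_by="IUI-71",
            first_concretized_at="t66",
        )
    )
    kb.add(
        ProcessRecord(
            "IUI-71",
            agent="IUI-63",
            agent_is_human=True,
            inputs=frozenset({"IUI-72", "IUI-73"}),  # no clinical picture, no aggregate
            outputs=frozenset({"IUI-66", "IUI-68"}),
            occupies="t71",
        )
    )
    R = RelationAssertion
    kb.add(R("IUI-64", "part_of", "IUI-63", "t64"))
    kb.add(R("IUI-65", "part_of", "IUI-64", "t65"))
    kb.add(R("IUI-66", "inheres_in", "IUI-65", "t66"))
    kb.add(R("IUI-66", "concretizes", "IUI-68", "t66"))
    kb.add(R("IUI-63", "agent_in", "IUI-71", "t71"))
    kb.add(R("IUI-72", "input_into", "IUI-71", "t71"))
    kb.add(R("IUI-73", "input_into", "IUI-71", "t71"))
    kb.add(R("IUI-66", "output_of", "IUI-71", "t66"))
    kb.add(R("IUI-68", "output_of", "IUI-71", "t66"))
    from .aboutness import infer_aboutness_relations

    for a in infer_aboutness_relations(kb.representations["IUI-66"], kb):
        kb.add(a)
    return "IUI-68"


def _scenario_5(kb: KnowledgeBase, variant: str) -> str:
    """The daughter's letter: her own belief, or a verbatim copy."""
    _regions(kb, "t83", "t89")
    kb.add(Particular("IUI-83", "Mr. Jones' daughter", "t83"))  # placeholder
    kb.add(Particular("IUI-89", "sentence in the daughter's letter", "t89"))
    if variant == "copy":
        # 'Dr. Smith says: …' followed by the sentence word for word; the
        # inscription concretizes Dr. Smith's diagnosis IUI-8, no new ICE
        copy = copy_concretization(
            kb.representations["IUI-10"], "IUI-89", "inscription_quality", kb, rep_id="IUI-92"
        )  # placeholder id
        return copy.id
    _regions(kb, "t84", "t85", "t86", "t87", "t88", "t90", "t91")
    kb.add(TemporalConstraint("t88", "during", "t2"))
    kb.add(Particular("IUI-84", "cognitive system of IUI-83", "t84"))  # placeholder
    kb.add(Particular("IUI-85", "anatomical entity, part of IUI-84", "t85"))  # placeholder
    kb.add(Particular("IUI-91", "the daughter's observations of her father", "t91"))  # placeholder
    kb.add(
        RepresentationRecord(
            "IUI-86", "cognitive", bearer="IUI-85", concretizes="IUI-88", exists_during="t86"
        )
    )  # placeholder id
    kb.add(
        RepresentationRecord(
            "IUI-90", "inscription_quality", bearer="IUI-89", concretizes="IUI-88", exists_during="t90"
        )
    )  # placeholder id
    content = AssertionContent(
        asserted_organism="IUI-1",
        asserted_disease="IUI-2",
        asserted_type="UUI-1",
        asserted_anchor="t88",
        intended_target="IUI-7",
    )
    kb.add(
        ICERecord(
            "IUI-88",
            content=content,
            concretizations=frozenset({"IUI-86", "IUI-90"}),
            produced_by="IUI-87",
            first_concretized_at="t86",
        )
    )
    kb.add(
        ProcessRecord(
            "IUI-87",  # placeholder id
            agent="IUI-83",
            agent_is_human=True,
            # Dr. Smith's diagnosis plus her own observations; no clinical
            # picture and no aggregate of disease-type representations
            inputs=frozenset({"IUI-8", "IUI-91"}),
            outputs=frozenset({"IUI-86", "IUI-88"}),
            occupies="t87",
        )
    )
    R = RelationAssertion
    kb.add(R("IUI-84", "part_of", "IUI-83", "t84"))
    kb.add(R("IUI-85", "part_of", "IUI-84", "t85"))
    kb.add(R("IUI-86", "inheres_in", "IUI-85", "t86"))
    kb.add(R("IUI-86", "concretizes", "IUI-88", "t86"))
    kb.add(R("IUI-90", "inheres_in", "IUI-89", "t90"))
    kb.add(R("IUI-90", "concretizes", "IUI-88", "t90"))
    kb.add(R("IUI-90", "is_conformant_to", "IUI-86", "t90"))
    kb.add(R("IUI-83", "agent_in", "IUI-87", "t87"))
    kb.add(R("IUI-8", "input_into", "IUI-87", "t87"))
    kb.add(R("IUI-91", "input_into", "IUI-87", "t87"))
    kb.add(R("IUI-86", "output_of", "IUI-87", "t86"))
    kb.add(R("IUI-88", "output_of", "IUI-87", "t86"))
    from .aboutness import infer_aboutness_relations

    for rep in ("IUI-86", "IUI-90"):
        for a in infer_aboutness_relations(kb.representations[rep], kb):
            kb.add(a)
    return "IUI-88"


def _scenario_6(kb: KnowledgeBase) -> str:
    """Diagnosis by a computer-based expert system: digital representations
    in place of cognitive ones; the definitions are agent-kind agnostic."""
    kb.add(Universal("UUI-3", "hyperglycemia (associated phenotype)"))  # placeholder
    _regions(kb, "t101", "t102", "t103", "t104", "t105", "t106", "t107", "t109", "t110", "t111")
    kb.add(TemporalConstraint("t105", "during", "t2"))
    for iui, label, tid in [  # all placeholder ids
        ("IUI-101", "the medical student", "t101"),
        ("IUI-102", "the diagnostic expert system", "t102"),
        ("IUI-103", "storage medium (hard drive / memory chips)", "t103"),
        ("IUI-109", "findings typed in by the medical student", "t109"),
        ("IUI-110", "printed sentence on paper", "t110"),
    ]:
        kb.add(Particular(iui, label, tid))
    kb.add(
        RepresentationRecord(
            "IUI-104", "digital", bearer="IUI-103", concretizes="IUI-105", exists_during="t104"
        )
    )
    kb.add(
        RepresentationRecord(
            "IUI-111", "inscription_quality", bearer="IUI-110", concretizes="IUI-105", exists_during="t111"
        )
    )
    content = AssertionContent(
        asserted_organism="IUI-1",
        asserted_disease="IUI-2",
        asserted_type="UUI-1",
        asserted_anchor="t105",
        intended_target="IUI-7",
    )
    kb.add(
        ICERecord(
            "IUI-105",
            content=content,
            concretizations=frozenset({"IUI-104", "IUI-111"}),
            produced_by="IUI-106",
            first_concretized_at="t104",
        )
    )
    kb.add(
        ClinicalPictureRecord(
            "IUI-107", subject="IUI-1", inferred_from=frozenset({"IUI-109"}), exists_during="t107"
        )
    )
    kb.add(
        KnowledgeAggregate(
            "IUI-108",
            disease_types=frozenset({"UUI-1"}),
            phenotype_types=frozenset({"UUI-3"}),
            owner="IUI-102",
        )
    )
    kb.add(
        ProcessRecord(
            "IUI-106",
            agent="IUI-102",
            agent_is_human=False,
            inputs=frozenset({"IUI-107", "IUI-108"}),
            outputs=frozenset({"IUI-104", "IUI-105"}),
            occupies="t106",
        )
    )
    R = RelationAssertion
    kb.add(R("IUI-104", "inheres_in", "IUI-103", "t104"))
    kb.add(R("IUI-104", "concretizes", "IUI-105", "t104"))
    kb.add(R("IUI-111", "inheres_in", "IUI-110", "t111"))
    kb.add(R("IUI-111", "concretizes", "IUI-105", "t111"))
    kb.add(R("IUI-111", "is_conformant_to", "IUI-104", "t111"))
    kb.add(R("IUI-102", "agent_in", "IUI-106", "t106"))
    kb.add(R("IUI-107", "input_into", "IUI-106", "t106"))
    kb.add(R("IUI-108", "input_into", "IUI-106", "t106"))
    kb.add(R("IUI-104", "output_of", "IUI-106", "t104"))
    kb.add(R("IUI-105", "output_of", "IUI-106", "t104"))
    from .aboutness import infer_aboutness_relations

    for rep in ("IUI-104", "IUI-111"):
        for a in infer_aboutness_relations(kb.representations[rep], kb):
            kb.add(a)
    return "IUI-105"


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def perturb(kb: KnowledgeBase, spec: PerturbationSpec) -> tuple[KnowledgeBase, AssertionContent]:
    """Inject exactly one fault matching ``spec.mode`` into the KB's
    assertion-under-test; the input KB is left unchanged.

    Returns the edited copy and the perturbed content (also installed on the
    ICE under test in the copy).
    """
    target = kb.metadata.get("ice_under_test")
    if target is None or target not in kb.ices:
        raise ValueError("perturb requires a scenario KB with a diagnosis ICE under test")
    out = kb.copy()
    ice = out.ices[target]
    content = ice.content
    mode = spec.mode

    if mode is FailureMode.NONINST_TYPE_EXISTS:
        actual = content.asserted_type
        other = next(
            (u for u in sorted(out.universals) if u != actual and out.universals[u].exists_flag and u != "UUI-3" and u != "UUI-4"),
            None,
        )
        if other is None:
            other = "UUI-2"
            out.add(Universal("UUI-2", "type 1 diabetes mellitus"))
        content = replace(content, asserted_type=other)
    elif mode is FailureMode.NONINST_TYPE_NONEXISTENT:
        out.add(Universal("UUI-99", "dropsy", exists_flag=False))
        content = replace(content, asserted_type="UUI-99")
    elif mode is FailureMode.DISEASE_NONEXISTENT:
        content = replace(content, asserted_disease="IUI-666")
    elif mode is FailureMode.ORGANISM_NONEXISTENT:
        content = replace(content, asserted_organism="IUI-777")
    elif mode is FailureMode.NON_INHERENCE:
        # the doctor mistakenly ascribes the disease to a twin
        out.add(TemporalRegion("t95"))
        out.add(Particular("IUI-95", "the patient's twin", "t95"))
        content = replace(content, asserted_organism="IUI-95")
    elif mode is FailureMode.SPACETIME_MISPLACEMENT:
        # anchored to a period entailed disjoint from the configuration's
        config = out.configurations[content.intended_target]
        out.add(TemporalRegion("t99"))
        out.add(TemporalConstraint("t99", "before", config.anchor))
        content = replace(content, asserted_anchor="t99")
    else:  # pragma: no cover
        raise ValueError(f"mode inapplicable: {mode}")

    out.replace_ice(replace(ice, content=content))
    out.metadata["perturbation"] = {"mode": mode.value, "seed": spec.seed, "target": spec.target}
    return out, content


# ---------------------------------------------------------------------------
# Synthetic KBs with constructively known labels
# ---------------------------------------------------------------------------

_HAPPY = (
    Category.CORRECT_DIAGNOSIS,
    Category.LUCKY_GUESS,
    Category.JUSTIFIED_CONCLUSION,
    Category.HEARSAY_COPY,
)

_COMPOUND_FAULTS = (
    FailureMode.NONINST_TYPE_EXISTS,
    FailureMode.NONINST_TYPE_NONEXISTENT,
    FailureMode.DISEASE_NONEXISTENT,
    FailureMode.NON_INHERENCE,
    FailureMode.SPACETIME_MISPLACEMENT,
)


def random_scenario(
    seed: int, n_particulars: int, fault_rate: float
) -> tuple[KnowledgeBase, list[tuple[str, Category]]]:
    """Seeded synthetic KB plus (target id, expected category) pairs.

    Expected categories are computed constructively while building — a case
    labelled ``misdiagnosis`` is built by wiring a diagnostic process to a
    content with one injected compound-level fault — never by running the
    classifier.  With ``fault_rate`` 0 every expected label is a happy one.
    """
    if n_particulars < 3:
        raise ValueError("n_particulars must be >= 3")
    rng = random.Random(seed)
    kb = KnowledgeBase()
    kb.metadata.update({"synthetic": True, "seed": seed})
    counter = [0]

    def iui() -> str:
        counter[0] += 1
        return f"IUI-{1000 + counter[0]}"

    def tid() -> str:
        counter[0] += 1
        return f"t{1000 + counter[0]}"

    n_types = max(2, n_particulars // 4)
    types = []
    for k in range(n_types):
        u = f"UUI-{100 + k}"
        kb.add(Universal(u, f"disease type {k}"))
        types.append(u)
    fake_type = "UUI-999"
    kb.add(Universal(fake_type, "nonexistent type", exists_flag=False))
    phen = "UUI-500"
    kb.add(Universal(phen, "phenotype type"))

    n_org = max(2, n_particulars // 3)
    organisms = []
    for _ in range(n_org):
        o_t, d_t = tid(), tid()
        kb.add(TemporalRegion(o_t))
        kb.add(TemporalRegion(d_t))
        kb.add(TemporalConstraint(d_t, "during", o_t))
        o, d = iui(), iui()
        kb.add(Particular(o, "organism", o_t))
        kb.add(Particular(d, "disease", d_t))
        dtype = rng.choice(types)
        kb.add(InstantiationAssertion(d, dtype, d_t))
        kb.add(RelationAssertion(d, "inheres_in", o, d_t))
        cfg = iui()
        kb.add(make_configuration(o, d, dtype, d_t, config_id=cfg, declared=kb.declared_ids()))
        organisms.append((o, d, dtype, d_t, cfg))

    expected: list[tuple[str, Category]] = []
    n_cases = max(2, n_particulars // 2)
    for _ in range(n_cases):
        o, d, dtype, d_t, cfg = rng.choice(organisms)
        base = rng.choice(_HAPPY)
        faulty = rng.random() < fault_rate

        agent_t = tid()
        kb.add(TemporalRegion(agent_t))
        agent = iui()
        kb.add(Particular(agent, "asserting agent", agent_t))
        bearer = iui()
        kb.add(Particular(bearer, "bearer", agent_t))

        content = AssertionContent(
            asserted_organism=o,
            asserted_disease=d,
            asserted_type=dtype,
            asserted_anchor=d_t,
            intended_target=cfg,
        )
        label = base
        if faulty:
            fault = rng.choice(_COMPOUND_FAULTS)
            if fault is FailureMode.NONINST_TYPE_EXISTS:
                wrong = rng.choice([u for u in types if u != dtype])
                content = replace(content, asserted_type=wrong)
            elif fault is FailureMode.NONINST_TYPE_NONEXISTENT:
                content = replace(content, asserted_type=fake_type)
            elif fault is FailureMode.DISEASE_NONEXISTENT:
                content = replace(content, asserted_disease=f"IUI-{9000 + counter[0]}")
            elif fault is FailureMode.NON_INHERENCE:
                others = [x for x in organisms if x[0] != o]
                if others:
                    content = replace(content, asserted_organism=rng.choice(others)[0])
                else:
                    content = replace(content, asserted_type=fake_type)
            else:  # SPACETIME_MISPLACEMENT
                off = tid()
                kb.add(TemporalRegion(off))
                kb.add(TemporalConstraint(off, "before", d_t))
                content = replace(content, asserted_anchor=off)
            # only a diagnostic pedigree turns the fault into a misdiagnosis;
            # otherwise the base category keeps its label (misinformation
            # counterpart) — hearsay copies likewise stay hearsay
            if base is Category.CORRECT_DIAGNOSIS:
                label = Category.MISDIAGNOSIS

        rep = RepresentationRecord(
            iui(), "cognitive", bearer=bearer, concretizes=None, exists_during=agent_t
        )
        proc_id = iui()
        inputs: set[str] = set()
        if base is Category.CORRECT_DIAGNOSIS:
            pic, agg, fnd = iui(), iui(), iui()
            kb.add(Particular(fnd, "finding", agent_t))
            kb.add(ClinicalPictureRecord(pic, subject=o, inferred_from=frozenset({fnd}), exists_during=agent_t))
            kb.add(KnowledgeAggregate(agg, frozenset({dtype if content.asserted_type != fake_type else types[0]}), frozenset({phen}), owner=agent))
            inputs = {pic, agg}
        elif base is Category.JUSTIFIED_CONCLUSION:
            # a prior diagnosis (itself correct, diagnostic pedigree) as input
            prior = _mk_prior_diagnosis(kb, iui, tid, o, d, dtype, d_t, cfg, phen)
            inputs = {prior}
        ice_id = iui()
        rep = replace(rep, concretizes=ice_id)
        kb.add(rep)
        kb.add(
            ProcessRecord(
                proc_id,
                agent=agent,
                agent_is_human=rng.random() < 0.8,
                inputs=frozenset(inputs),
                outputs=frozenset({rep.id, ice_id}),
                occupies=agent_t,
            )
        )
        ice = ICERecord(
            ice_id,
            content=content,
            concretizations=frozenset({rep.id}),
            produced_by=proc_id,
            first_concretized_at=agent_t,
        )
        kb.add(ice)
        if base is Category.HEARSAY_COPY:
            carrier = iui()
            kb.add(Particular(carrier, "copy bearer", agent_t))
            copy = copy_concretization(rep, carrier, "inscription_quality", kb, rep_id=iui())
            # the copy is hearsay whatever the content's fate; but the copied
            # ICE here has no diagnostic pedigree, so keep the label on the copy
            expected.append((copy.id, Category.HEARSAY_COPY))
            continue
        expected.append((ice_id, label))
    return kb, expected


def _mk_prior_diagnosis(kb, iui, tid, o, d, dtype, d_t, cfg, phen) -> str:
    """A correct, diagnostically produced prior ICE to feed a layperson."""
    t = tid()
    kb.add(TemporalRegion(t))
    doc, bearer, fnd, pic, agg, proc, ice_id = (iui() for _ in range(7))
    kb.add(Particular(doc, "prior physician", t))
    kb.add(Particular(bearer, "prior bearer", t))
    kb.add(Particular(fnd, "prior finding", t))
    kb.add(ClinicalPictureRecord(pic, subject=o, inferred_from=frozenset({fnd}), exists_during=t))
    kb.add(KnowledgeAggregate(agg, frozenset({dtype}), frozenset({phen}), owner=doc))
    rep = RepresentationRecord(iui(), "cognitive", bearer=bearer, concretizes=ice_id, exists_during=t)
    kb.add(rep)
    kb.add(
        ProcessRecord(
            proc, agent=doc, agent_is_human=True,
            inputs=frozenset({pic, agg}), outputs=frozenset({rep.id, ice_id}), occupies=t,
        )
    )
    kb.add(
        ICERecord(
            ice_id,
            content=AssertionContent(
                asserted_organism=o, asserted_disease=d, asserted_type=dtype,
                asserted_anchor=d_t, intended_target=cfg,
            ),
            concretizations=frozenset({rep.id}),
            produced_by=proc,
            first_concretized_at=t,
        )
    )
    return ice_id
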