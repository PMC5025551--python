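"""Provenance-aware classification of diagnostic assertions.

Distinguishes, for an information content entity asserting that an organism
has a disease of a certain type:

* **correct diagnosis** — output of a diagnostic process, compound aboutness
  holds;
* **misdiagnosis** — output of a diagnostic process, compound aboutness
  fails; annotated with the six single-fault failure modes and where the
  failure first appears (reference vs. compound level);
* **lucky guess** — coincidentally correct, but not produced by a diagnostic
  process and without epistemically relevant inputs;
* **hearsay/copy** — a representation produced by copying, concretizing the
  original ICE;
* **justified conclusion** — a layperson's belief derived from a prior
  diagnosis, correct but not a diagnosis;
* **non-ICE** — fails in aboutness on every referent, hence about nothing.

A diagnostic process requires as input both a clinical picture of the
patient and an aggregate of representations of at least one disease type
together with at least one associated phenotype type; nothing requires the
agent to be human.
"""

from __future__ import annotations

import logging
from typing import Collection, Mapping, Optional

from .aboutness import evaluate_compound, evaluate_reference
from .core_model import (
    AssertionContent,
    Category,
    ClassificationResult,
    FailureMode,
    ICERecord,
    ProcessRecord,
    REFERENCE_LEVEL_MODES,
    RepresentationRecord,
    Verdict,
)
from .errors import DeclarationError
from .kb_store import KnowledgeBase
from .provenance import is_copy

__all__ = [
    "is_diagnostic_process",
    "classify_failure_modes",
    "classify_assertion",
    "classify_target",
    "check_precision",
]

logger = logging.getLogger(__name__)


def is_diagnostic_process(process: ProcessRecord, kb: KnowledgeBase) -> Verdict:
    """Whether the process qualifies as a diagnostic process.

    Holds iff its inputs include (1) a clinical picture of some organism and
    (2) a knowledge aggregate pairing at least one disease type with at least
    one associated phenotype type.  Agent kind is irrelevant.  The KB is
    closed-world, so the answer is never indeterminate.
    """
    if process.id not in kb.processes:
        raise DeclarationError(process.id, "is_diagnostic_process")
    has_picture = any(i in kb.clinical_pictures for i in process.inputs)
    has_aggregate = any(
        i in kb.knowledge_aggregates
        and kb.knowledge_aggregates[i].disease_types
        and kb.knowledge_aggregates[i].phenotype_types
        for i in process.inputs
    )
    return Verdict.HOLDS if (has_picture and has_aggregate) else Verdict.FAILS


def classify_failure_modes(
    content: AssertionContent, kb: KnowledgeBase
) -> tuple[frozenset[FailureMode], str]:
    """All applicable failure modes plus where the failure first appears.

    ``fails_first`` is ``reference`` when any of the three nonexistence modes
    applies, ``compound`` when only configuration-level modes apply, and
    ``none`` for a fault-free content.
    """
    modes: set[FailureMode] = set()

    organism_ok = content.asserted_organism is not None and kb.is_particular(
        content.asserted_organism
    )
    disease_ok = content.asserted_disease is not None and kb.is_particular(
        content.asserted_disease
    )
    u = kb.universals.get(content.asserted_type)
    type_exists = u is not None and u.exists_flag

    if not organism_ok:
        modes.add(FailureMode.ORGANISM_NONEXISTENT)
    if not disease_ok:
        modes.add(FailureMode.DISEASE_NONEXISTENT)
    if disease_ok and not kb.entails_relation(
        content.asserted_disease, "instance_of", content.asserted_type
    ):
        # the disease instantiates a different type than stated
        if type_exists:
            modes.add(FailureMode.NONINST_TYPE_EXISTS)
        else:
            modes.add(FailureMode.NONINST_TYPE_NONEXISTENT)
    elif not type_exists:
        modes.add(FailureMode.NONINST_TYPE_NONEXISTENT)
    if (
        organism_ok
        and disease_ok
        and not kb.entails_relation(content.asserted_disease, "inheres_in", content.asserted_organism)
    ):
        modes.add(FailureMode.NON_INHERENCE)
    config = kb.configurations.get(content.intended_target)
    if (
        config is not None
        and content.asserted_anchor in kb.temporal_regions
        and kb.entails_temporal(content.asserted_anchor, "overlaps", config.anchor) is Verdict.FAILS
    ):
        modes.add(FailureMode.SPACETIME_MISPLACEMENT)

    if modes & REFERENCE_LEVEL_MODES:
        fails_first = "reference"
    elif modes:
        fails_first = "compound"
    else:
        fails_first = "none"
    return frozenset(modes), fails_first


def _has_prior_diagnosis_input(process: Optional[ProcessRecord], kb: KnowledgeBase) -> bool:
    """Whether a prior diagnosis ICE figures among the process inputs, either
    directly (alongside the clinical picture) or inside a clinical picture's
    inference base.  Both placements count."""
    if process is None:
        return False
    for i in process.inputs:
        if i in kb.ices:
            return True
        pic = kb.clinical_pictures.get(i)
        if pic is not None and any(x in kb.ices for x in pic.inferred_from):
            return True
    return False


def classify_assertion(
    ice: ICERecord,
    kb: KnowledgeBase,
    *,
    via: Optional[RepresentationRecord] = None,
) -> ClassificationResult:
    """Classify one diagnostic assertion against the KB.

    ``via`` names the concretization through which the assertion is under
    scrutiny; when that representation was produced by copying, the verdict
    is hearsay regardless of the original ICE's pedigree.
    """
    rationale: list[str] = []
    content = ice.content

    reference = evaluate_reference(content, kb)
    if reference.status is Verdict.FAILS:
        # about nothing at all: not an ICE, let alone a diagnosis
        modes, fails_first = classify_failure_modes(content, kb)
        rationale.append("R1: every referent fails at the level of reference")
        return ClassificationResult(Category.NON_ICE, modes, fails_first, tuple(rationale))
    rationale.append("R0: at least one referent holds; the assertion is an ICE")

    modes, fails_first = classify_failure_modes(content, kb)
    compound = evaluate_compound(content, kb)

    if via is not None and is_copy(via):
        rationale.append(f"R2: representation {via.id} was produced by copying {via.copied_from}")
        if compound.status is Verdict.FAILS:
            rationale.append(
                "R11: compound aboutness fails; misinformation counterpart with modes "
                + ",".join(sorted(m.value for m in modes))
            )
        return ClassificationResult(
            Category.HEARSAY_COPY,
            frozenset(),
            "none" if compound.status is Verdict.HOLDS else fails_first,
            tuple(rationale),
        )

    process = None
    if ice.produced_by is not None:
        if ice.produced_by not in kb.processes:
            raise DeclarationError(ice.produced_by, f"ICE {ice.id} produced_by")
        process = kb.processes[ice.produced_by]

    organism_missing = FailureMode.ORGANISM_NONEXISTENT in modes
    if organism_missing:
        # no organism, hence no clinical picture could have been inferred:
        # neither a diagnosis nor a misdiagnosis, whatever the process looks like
        rationale.append("R3: asserted organism does not exist; no clinical picture is possible")

    diagnostic = (
        process is not None
        and not organism_missing
        and is_diagnostic_process(process, kb) is Verdict.HOLDS
    )

    if diagnostic:
        rationale.append(f"R4: producing process {process.id} is a diagnostic process")
        if compound.status is Verdict.HOLDS:
            rationale.append("R5: compound aboutness holds -> correct diagnosis")
            return ClassificationResult(Category.CORRECT_DIAGNOSIS, frozenset(), "none", tuple(rationale))
        if compound.status is Verdict.FAILS:
            rationale.append("R6: compound aboutness fails -> misdiagnosis")
            return ClassificationResult(Category.MISDIAGNOSIS, modes, fails_first, tuple(rationale))
        rationale.append("R7: temporal placement unsettled -> indeterminate")
        return ClassificationResult(Category.INDETERMINATE, frozenset(), fails_first, tuple(rationale))

    rationale.append("R8: no diagnostic process produced this assertion")
    if compound.status is Verdict.INDETERMINATE:
        rationale.append("R7: temporal placement unsettled -> indeterminate")
        return ClassificationResult(Category.INDETERMINATE, frozenset(), fails_first, tuple(rationale))

    informed = _has_prior_diagnosis_input(process, kb)
    if informed:
        rationale.append("R9: a prior diagnosis figures among the inputs -> justified conclusion")
        category = Category.JUSTIFIED_CONCLUSION
    else:
        rationale.append("R10: no epistemically relevant inputs -> lucky guess")
        category = Category.LUCKY_GUESS
    if compound.status is Verdict.FAILS:
        # misinformation counterpart: base category kept, faults go on record
        rationale.append(
            "R11: compound aboutness fails; misinformation counterpart with modes "
            + ",".join(sorted(m.value for m in modes))
        )
    return ClassificationResult(category, frozenset(), "none" if compound.status is Verdict.HOLDS else fails_first, tuple(rationale))


def classify_target(kb: KnowledgeBase, target_id: str) -> ClassificationResult:
    """Classify by identifier: an ICE id directly, or a representation id
    (scrutinized via that representation, so copies classify as hearsay)."""
    if target_id in kb.ices:
        return classify_assertion(kb.ices[target_id], kb)
    if target_id in kb.representations:
        rep = kb.representations[target_id]
        if rep.concretizes is None or rep.concretizes not in kb.ices:
            raise DeclarationError(str(rep.concretizes), f"representation {target_id}")
        return classify_assertion(kb.ices[rep.concretizes], kb, via=rep)
    raise DeclarationError(target_id, "unknown ICE")


def check_precision(
    content: AssertionContent,
    type_hierarchy: Mapping[str, str],
    root: str,
    *,
    too_general: Collection[str] = (),
) -> Optional[str]:
    """Warn (never fail) when the asserted type is trivially general.

    ``type_hierarchy`` maps each type to its parent; ``too_general`` is a
    configurable stratum of types judged clinically useless for treatment.
    """
    if not type_hierarchy:
        logger.info("check_precision: empty type hierarchy; nothing to check")
        return None
    t = content.asserted_type
    if t == root or t in set(too_general):
        return (
            f"asserted type {t} is too general to guide treatment or prognosis; "
            "state the most specific type known"
        )
    return None
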