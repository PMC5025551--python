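"""Two-level aboutness evaluation.

A diagnostic content can succeed or fail in aboutness at two levels: the
level of *reference* (does each mentioned referent denote something that
exists?) and the level of *compound expression* (does the configuration as a
whole exist as asserted?).  Reference failure on every referent means the
content is not about anything at all; reference failure on any referent
forces compound failure, because a configuration cannot consist of that
which does not exist.
"""

from __future__ import annotations

from .core_model import (
    AboutnessVerdict,
    AssertionContent,
    RelationAssertion,
    RepresentationRecord,
    Verdict,
)
from .errors import DeclarationError
from .kb_store import KnowledgeBase

__all__ = [
    "evaluate_reference",
    "evaluate_compound",
    "infer_aboutness_relations",
]


def _referent_verdicts(content: AssertionContent, kb: KnowledgeBase) -> dict[str, Verdict]:
    """Per-referent reference-level verdicts for the non-null mentions.

    An organism/disease mention holds iff it denotes a declared particular;
    a type mention holds iff it denotes a declared universal taken to exist.
    Closed world: what is not declared does not exist in this scenario.
    """
    out: dict[str, Verdict] = {}
    if content.asserted_organism is not None:
        out[content.asserted_organism] = (
            Verdict.HOLDS if kb.is_particular(content.asserted_organism) else Verdict.FAILS
        )
    if content.asserted_disease is not None:
        out[content.asserted_disease] = (
            Verdict.HOLDS if kb.is_particular(content.asserted_disease) else Verdict.FAILS
        )
    u = kb.universals.get(content.asserted_type)
    out[content.asserted_type] = (
        Verdict.HOLDS if u is not None and u.exists_flag else Verdict.FAILS
    )
    return out


def evaluate_reference(content: AssertionContent, kb: KnowledgeBase) -> AboutnessVerdict:
    """Reference-level verdict: holds iff at least one referent denotes.

    A content that refers to *something* is an information content entity
    even if the compound it expresses never existed.
    """
    per = _referent_verdicts(content, kb)
    status = Verdict.HOLDS if any(v is Verdict.HOLDS for v in per.values()) else Verdict.FAILS
    return AboutnessVerdict(level="reference", per_referent=per, status=status)


def evaluate_compound(content: AssertionContent, kb: KnowledgeBase) -> AboutnessVerdict:
    """Compound-level verdict against the intended target configuration.

    Holds iff (a) every mentioned referent holds at reference level, (b) the
    KB entails that the asserted disease inheres in the asserted organism and
    instantiates the asserted type, and (c) the asserted spacetime anchor is
    entailed to intersect the configuration's anchor.  Indeterminate exactly
    when (a) and (b) hold but the temporal placement is unsettled.
    """
    per = _referent_verdicts(content, kb)
    if any(v is Verdict.FAILS for v in per.values()) or not per:
        return AboutnessVerdict(level="compound", per_referent=per, status=Verdict.FAILS)
    structural = (
        content.asserted_organism is not None
        and content.asserted_disease is not None
        and kb.entails_relation(content.asserted_disease, "inheres_in", content.asserted_organism)
        and kb.entails_relation(content.asserted_disease, "instance_of", content.asserted_type)
    )
    if not structural:
        return AboutnessVerdict(level="compound", per_referent=per, status=Verdict.FAILS)
    config = kb.configurations.get(content.intended_target)
    if config is None:
        return AboutnessVerdict(level="compound", per_referent=per, status=Verdict.FAILS)
    # the diagnosis must refer to some part, not necessarily the entirety,
    # of the spacetime occupied by the configuration
    if content.asserted_anchor not in kb.temporal_regions:
        # unknown region: placement cannot be settled either way
        return AboutnessVerdict(level="compound", per_referent=per, status=Verdict.INDETERMINATE)
    temporal = kb.entails_temporal(content.asserted_anchor, "overlaps", config.anchor)
    status = {
        Verdict.HOLDS: Verdict.HOLDS,
        Verdict.FAILS: Verdict.FAILS,
        Verdict.INDETERMINATE: Verdict.INDETERMINATE,
    }[temporal]
    return AboutnessVerdict(level="compound", per_referent=per, status=status)


def infer_aboutness_relations(
    representation: RepresentationRecord, kb: KnowledgeBase
) -> frozenset[RelationAssertion]:
    """Derive is_about / is_misrepresentation_of assertions for a representation.

    Emits ``is_about`` toward every referent that holds at reference level,
    ``is_about`` toward the intended target when the compound holds, and
    ``is_misrepresentation_of`` toward the intended target when it fails
    (intended to be about it, but not about it).  An indeterminate compound
    emits neither toward the target.
    """
    if representation.concretizes is None or representation.concretizes not in kb.ices:
        raise DeclarationError(
            str(representation.concretizes), f"representation {representation.id} concretizes no known ICE"
        )
    ice = kb.ices[representation.concretizes]
    content = ice.content
    at = representation.exists_during
    out: set[RelationAssertion] = set()
    for referent, verdict in _referent_verdicts(content, kb).items():
        if verdict is Verdict.HOLDS:
            out.add(RelationAssertion(representation.id, "is_about", referent, at))
    compound = evaluate_compound(content, kb)
    if compound.status is Verdict.HOLDS:
        out.add(RelationAssertion(representation.id, "is_about", content.intended_target, at))
    elif compound.status is Verdict.FAILS:
        out.add(
            RelationAssertion(
                representation.id, "is_misrepresentation_of", content.intended_target, at
            )
        )
    return frozenset(out)
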