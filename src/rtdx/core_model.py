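"""Shared domain types for referent-tracking knowledge bases.

Pure data model: no I/O, no inference.  Every entity that exists is a
*particular* carrying an instance unique identifier (``IUI-n``); repeatable
types are *universals* (``UUI-n``); temporal regions carry identifiers of the
form ``tn``.  Distinct temporal identifiers may denote the same underlying
period, so identity of periods is never inferred from identifier distinctness.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Union

from .errors import DeclarationError

__all__ = [
    "IUI_RE",
    "UUI_RE",
    "TID_RE",
    "TEMPORAL_RELATIONS",
    "RELATION_NAMES",
    "TYPE_TARGET_RELATIONS",
    "Particular",
    "Universal",
    "TemporalRegion",
    "TemporalConstraint",
    "InstantiationAssertion",
    "RelationAssertion",
    "NegativeAssertion",
    "Configuration",
    "AssertionContent",
    "RepresentationRecord",
    "ICERecord",
    "ProcessRecord",
    "KnowledgeAggregate",
    "ClinicalPictureRecord",
    "AboutnessVerdict",
    "ClassificationResult",
    "Category",
    "FailureMode",
    "Verdict",
    "is_iui",
    "is_uui",
    "is_tid",
    "make_configuration",
    "validate_record",
]

IUI_RE = re.compile(r"^IUI-\d+$")
UUI_RE = re.compile(r"^UUI-\d+$")
TID_RE = re.compile(r"^t\d+$")

#: Closed vocabulary of temporal constraint relations.
TEMPORAL_RELATIONS = frozenset(
    {"equals", "during", "contains", "ends", "starts", "before", "overlaps"}
)

#: Closed vocabulary of particular-to-particular relations.
RELATION_NAMES = frozenset(
    {
        "inheres_in",
        "bearer_of",
        "part_of",
        "is_about",
        "concretizes",
        "is_conformant_to",
        "is_misrepresentation_of",
        "agent_in",
        "input_into",
        "output_of",
    }
)

#: Relations whose object may be a universal or a configuration id, not only an IUI.
TYPE_TARGET_RELATIONS = frozenset({"is_about", "is_misrepresentation_of"})


def is_iui(s: object) -> bool:
    return isinstance(s, str) and IUI_RE.match(s) is not None


def is_uui(s: object) -> bool:
    return isinstance(s, str) and UUI_RE.match(s) is not None


def is_tid(s: object) -> bool:
    return isinstance(s, str) and TID_RE.match(s) is not None


class Verdict(str, enum.Enum):
    """Three-valued outcome used by temporal entailment and aboutness."""

    HOLDS = "holds"
    FAILS = "fails"
    INDETERMINATE = "indeterminate"


class Category(str, enum.Enum):
    """Classification outcomes for a diagnostic assertion."""

    CORRECT_DIAGNOSIS = "correct_diagnosis"
    MISDIAGNOSIS = "misdiagnosis"
    LUCKY_GUESS = "lucky_guess"
    HEARSAY_COPY = "hearsay_copy"
    JUSTIFIED_CONCLUSION = "justified_conclusion"
    NON_ICE = "non_ice"
    INDETERMINATE = "indeterminate"


class FailureMode(str, enum.Enum):
    """The six single-fault ways a diagnostic assertion can fail compound aboutness."""

    NONINST_TYPE_EXISTS = "NONINST_TYPE_EXISTS"
    NONINST_TYPE_NONEXISTENT = "NONINST_TYPE_NONEXISTENT"
    DISEASE_NONEXISTENT = "DISEASE_NONEXISTENT"
    ORGANISM_NONEXISTENT = "ORGANISM_NONEXISTENT"
    NON_INHERENCE = "NON_INHERENCE"
    SPACETIME_MISPLACEMENT = "SPACETIME_MISPLACEMENT"


#: Modes whose fault already breaks aboutness at the level of reference.
REFERENCE_LEVEL_MODES = frozenset(
    {
        FailureMode.NONINST_TYPE_NONEXISTENT,
        FailureMode.DISEASE_NONEXISTENT,
        FailureMode.ORGANISM_NONEXISTENT,
    }
)

#: Categories that, when assigned, carry no failure modes in the result field
#: (faults discovered along the way are reported in the rationale trail only).
CLEAN_CATEGORIES = frozenset(
    {
        Category.CORRECT_DIAGNOSIS,
        Category.LUCKY_GUESS,
        Category.HEARSAY_COPY,
        Category.JUSTIFIED_CONCLUSION,
    }
)


@dataclass(frozen=True)
class Particular:
    """A concrete individual entity, identified by an IUI."""

    iui: str
    label: str = ""
    existence_interval: str = ""  # tid; always present, possibly unconstrained


@dataclass(frozen=True)
class Universal:
    """A repeatable type, identified by a UUI.

    ``exists_flag`` records whether the type is taken to exist in reality;
    a declared-but-nonexistent universal (e.g. 'dropsy') keeps assertions
    that mention it parseable while letting evaluators treat the reference
    as failing.
    """

    uui: str
    label: str = ""
    exists_flag: bool = True


@dataclass(frozen=True)
class TemporalRegion:
    tid: str
    description: str = ""


@dataclass(frozen=True)
class TemporalConstraint:
    """``subject relation object`` over temporal region identifiers."""

    subject: str
    relation: str
    object: str


@dataclass(frozen=True)
class InstantiationAssertion:
    """``particular instance_of universal at tid``."""

    particular: str
    universal: str
    at: str


@dataclass(frozen=True)
class RelationAssertion:
    """``subject relation object at tid`` between declared referents."""

    subject: str
    relation: str
    object: str
    at: str


@dataclass(frozen=True)
class NegativeAssertion:
    """The particular stands in ``relation`` to NO instance of ``universal``
    throughout the region ``during``."""

    particular: str
    relation: str
    universal: str
    during: str


@dataclass(frozen=True)
class Configuration:
    """A combination of particulars and/or universals plus the relations that
    hold among them, anchored in spacetime.  Configurations are first-class
    particulars with their own IUIs."""

    id: str
    members_particulars: frozenset[str]
    members_universals: frozenset[str]
    constituent_relations: frozenset[Union[RelationAssertion, InstantiationAssertion]]
    anchor: str


@dataclass(frozen=True)
class AssertionContent:
    """What a diagnostic assertion says: organism, disease, type, and where in
    spacetime, plus the configuration the author intended to be about.

    ``intended_target`` is recorded data, never computed: authorial intention
    is not recoverable from the assertion itself.  The organism/disease fields
    are *mentions* and may name identifiers that are not declared in a KB
    (that is precisely how reference failure arises).
    """

    asserted_type: str
    asserted_anchor: str
    intended_target: str
    asserted_organism: Optional[str] = None
    asserted_disease: Optional[str] = None


@dataclass(frozen=True)
class RepresentationRecord:
    """A concretization of an ICE: cognitive, ink-on-paper, or digital."""

    id: str
    kind: str  # cognitive | inscription_quality | digital
    bearer: str
    concretizes: Optional[str]  # ICE id; None only transiently, before attachment
    exists_during: str
    copied_from: Optional[str] = None  # representation id this one was copied from

    KINDS = frozenset({"cognitive", "inscription_quality", "digital"})


@dataclass(frozen=True)
class ICERecord:
    """An information content entity: generically dependent content that exists
    only once its first concretization does."""

    id: str
    content: AssertionContent
    concretizations: frozenset[str]
    produced_by: Optional[str]  # process id
    first_concretized_at: str


@dataclass(frozen=True)
class ProcessRecord:
    id: str
    agent: str
    agent_is_human: bool
    inputs: frozenset[str]
    outputs: frozenset[str]
    occupies: str


@dataclass(frozen=True)
class KnowledgeAggregate:
    """An aggregate of an agent's representations of disease types and of the
    phenotype types associated with them.  Fit for use in diagnosing only when
    both sets are non-empty."""

    id: str
    disease_types: frozenset[str]
    phenotype_types: frozenset[str]
    owner: str


@dataclass(frozen=True)
class ClinicalPictureRecord:
    id: str
    subject: str  # the patient
    inferred_from: frozenset[str]  # findings and/or prior diagnosis ICEs
    exists_during: str


@dataclass(frozen=True)
class AboutnessVerdict:
    level: str  # reference | compound
    per_referent: Mapping[str, Verdict]
    status: Verdict

    def holding_referents(self) -> list[str]:
        return [r for r, v in self.per_referent.items() if v is Verdict.HOLDS]


@dataclass(frozen=True)
class ClassificationResult:
    category: Category
    failure_modes: frozenset[FailureMode]
    fails_first: str  # reference | compound | none
    rationale: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "category": self.category.value,
            "failure_modes": sorted(m.value for m in self.failure_modes),
            "fails_first": self.fails_first,
            "rationale": list(self.rationale),
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_configuration(
    organism: str,
    disease: str,
    disease_type: str,
    anchor: str,
    *,
    config_id: str,
    declared: Optional[Iterable[str]] = None,
) -> Configuration:
    """Build the organism/disease/type configuration anchored at ``anchor``.

    The constituent relations are exactly ``disease inheres_in organism`` and
    ``disease instance_of disease_type``, both indexed to the anchor.  When
    ``declared`` is given, every referent must appear in it.
    """
    if declared is not None:
        known = set(declared)
        for ref in (organism, disease, disease_type, anchor):
            if ref not in known:
                raise DeclarationError(ref, "make_configuration")
    return Configuration(
        id=config_id,
        members_particulars=frozenset({organism, disease}),
        members_universals=frozenset({disease_type}),
        constituent_relations=frozenset(
            {
                RelationAssertion(disease, "inheres_in", organism, anchor),
                InstantiationAssertion(disease, disease_type, anchor),
            }
        ),
        anchor=anchor,
    )


def _check_id(value: object, pred, what: str, out: list[str]) -> None:
    if not pred(value):
        out.append(f"{what}: malformed identifier {value!r}")


def validate_record(record: object) -> list[str]:
    """Return violation descriptors for one record; empty list iff well-formed.

    Only intra-record invariants are checked here; cross-record closure is the
    knowledge base's concern (``kb_store.check_consistency``).
    """
    v: list[str] = []
    if isinstance(record, Particular):
        _check_id(record.iui, is_iui, "Particular.iui", v)
        if not record.existence_interval:
            v.append(f"Particular {record.iui}: missing existence_interval")
        elif not is_tid(record.existence_interval):
            v.append(f"Particular {record.iui}: malformed existence_interval {record.existence_interval!r}")
    elif isinstance(record, Universal):
        _check_id(record.uui, is_uui, "Universal.uui", v)
    elif isinstance(record, TemporalRegion):
        _check_id(record.tid, is_tid, "TemporalRegion.tid", v)
    elif isinstance(record, TemporalConstraint):
        _check_id(record.subject, is_tid, "TemporalConstraint.subject", v)
        _check_id(record.object, is_tid, "TemporalConstraint.object", v)
        if record.relation not in TEMPORAL_RELATIONS:
            v.append(f"TemporalConstraint: unknown relation {record.relation!r}")
    elif isinstance(record, InstantiationAssertion):
        _check_id(record.particular, is_iui, "InstantiationAssertion.particular", v)
        _check_id(record.universal, is_uui, "InstantiationAssertion.universal", v)
        _check_id(record.at, is_tid, "InstantiationAssertion.at", v)
    elif isinstance(record, RelationAssertion):
        _check_id(record.subject, is_iui, "RelationAssertion.subject", v)
        _check_id(record.at, is_tid, "RelationAssertion.at", v)
        if record.relation not in RELATION_NAMES:
            v.append(f"RelationAssertion: unknown relation {record.relation!r}")
        elif record.relation in TYPE_TARGET_RELATIONS:
            if not (is_iui(record.object) or is_uui(record.object)):
                v.append(f"RelationAssertion.object: malformed identifier {record.object!r}")
        else:
            _check_id(record.object, is_iui, "RelationAssertion.object", v)
    elif isinstance(record, NegativeAssertion):
        _check_id(record.particular, is_iui, "NegativeAssertion.particular", v)
        _check_id(record.universal, is_uui, "NegativeAssertion.universal", v)
        _check_id(record.during, is_tid, "NegativeAssertion.during", v)
    elif isinstance(record, Configuration):
        _check_id(record.id, is_iui, "Configuration.id", v)
        if not record.anchor:
            v.append(f"Configuration {record.id}: missing anchor")
        referenced: set[str] = set()
        for rel in record.constituent_relations:
            if isinstance(rel, RelationAssertion):
                referenced.update({rel.subject, rel.object})
            else:
                referenced.update({rel.particular, rel.universal})
        for m in record.members_particulars | record.members_universals:
            if m not in referenced:
                v.append(f"Configuration {record.id}: member {m} not referenced by any constituent relation")
    elif isinstance(record, AssertionContent):
        if not record.intended_target:
            v.append("AssertionContent: missing intended_target")
        if not record.asserted_type:
            v.append("AssertionContent: missing asserted_type")
        if not record.asserted_anchor:
            v.append("AssertionContent: missing asserted_anchor")
    elif isinstance(record, RepresentationRecord):
        _check_id(record.id, is_iui, "RepresentationRecord.id", v)
        if record.kind not in RepresentationRecord.KINDS:
            v.append(f"RepresentationRecord {record.id}: unknown kind {record.kind!r}")
        if not record.bearer:
            v.append(f"RepresentationRecord {record.id}: missing bearer")
        if record.concretizes is None:
            v.append(f"RepresentationRecord {record.id}: not attached to any ICE")
    elif isinstance(record, ICERecord):
        _check_id(record.id, is_iui, "ICERecord.id", v)
        if not record.concretizations:
            # The ICE does not exist until its first concretization does.
            v.append(f"ICERecord {record.id}: no concretizations")
        v.extend(validate_record(record.content))
    elif isinstance(record, ProcessRecord):
        _check_id(record.id, is_iui, "ProcessRecord.id", v)
        if not record.agent:
            v.append(f"ProcessRecord {record.id}: missing agent")
    elif isinstance(record, KnowledgeAggregate):
        _check_id(record.id, is_iui, "KnowledgeAggregate.id", v)
        if not record.disease_types or not record.phenotype_types:
            v.append(
                f"KnowledgeAggregate {record.id}: unfit for diagnosing "
                "(needs >=1 disease type and >=1 associated phenotype type)"
            )
    elif isinstance(record, ClinicalPictureRecord):
        _check_id(record.id, is_iui, "ClinicalPictureRecord.id", v)
        if not record.subject:
            v.append(f"ClinicalPictureRecord {record.id}: missing subject")
    elif isinstance(record, AboutnessVerdict):
        if record.level == "compound" and record.status is not Verdict.FAILS:
            if any(x is Verdict.FAILS for x in record.per_referent.values()):
                v.append("AboutnessVerdict: compound status must fail when a reference-level entry fails")
    elif isinstance(record, ClassificationResult):
        if record.category in CLEAN_CATEGORIES and record.failure_modes:
            v.append(f"ClassificationResult: {record.category.value} must carry no failure modes")
        if record.category in (Category.MISDIAGNOSIS, Category.NON_ICE) and not record.failure_modes:
            v.append(f"ClassificationResult: {record.category.value} requires at least one failure mode")
    else:
        v.append(f"unknown record type: {type(record).__name__}")
    return v
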