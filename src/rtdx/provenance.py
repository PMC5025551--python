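"""ICE identity across concretizations.

Copying a representation yields a new concretization of the *same* ICE — no
comprehension of the content is required, as when copying text in a language
one does not read.  Creating one's own representation of a portion of
reality, by contrast, brings a new ICE into being even when the sentence
produced is word-for-word identical to someone else's: ICE identity is by
minted identifier and provenance, never by sentence text.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

from .core_model import (
    AssertionContent,
    ICERecord,
    ProcessRecord,
    RepresentationRecord,
    validate_record,
)
from .errors import DeclarationError, ValidationError
from .kb_store import KnowledgeBase

__all__ = ["copy_concretization", "derive_new_ice", "check_conformance", "is_copy"]


def copy_concretization(
    source: RepresentationRecord,
    new_bearer: str,
    kind: str,
    kb: KnowledgeBase,
    *,
    rep_id: Optional[str] = None,
) -> RepresentationRecord:
    """Copy ``source`` onto ``new_bearer``; the copy concretizes the same ICE.

    The KB's ICE count is unchanged.  The copy records its origin in
    ``copied_from``, which is what later marks it as hearsay.
    """
    if source.concretizes is None or source.concretizes not in kb.ices:
        raise DeclarationError(str(source.concretizes), "source concretizes no known ICE")
    if not kb.is_particular(new_bearer):
        raise DeclarationError(new_bearer, "copy bearer")
    new_id = rep_id or kb.mint_iui()
    copy = RepresentationRecord(
        id=new_id,
        kind=kind,
        bearer=new_bearer,
        concretizes=source.concretizes,
        exists_during=source.exists_during,
        copied_from=source.id,
    )
    kb.add(copy)
    ice = kb.ices[source.concretizes]
    kb.replace_ice(replace(ice, concretizations=ice.concretizations | {new_id}))
    return copy


def derive_new_ice(
    author: str,
    producing_process: ProcessRecord,
    content: AssertionContent,
    first_concretization: RepresentationRecord,
    kb: KnowledgeBase,
    *,
    ice_id: Optional[str] = None,
) -> ICERecord:
    """Mint a new ICE for a freshly authored representation.

    ``first_concretization`` must not yet concretize anything; the ICE begins
    to exist when this representation does.  The KB's ICE count increases by
    exactly one.
    """
    if first_concretization.concretizes is not None:
        raise ValidationError(
            f"representation {first_concretization.id} already concretizes "
            f"{first_concretization.concretizes}"
        )
    problems = validate_record(content)
    if problems:
        raise ValidationError("; ".join(problems))
    if not kb.is_particular(author):
        raise DeclarationError(author, "ICE author")
    new_id = ice_id or kb.mint_iui()
    attached = replace(first_concretization, concretizes=new_id)
    kb.add(attached)
    if producing_process.id not in kb.processes:
        kb.add(producing_process)
    ice = ICERecord(
        id=new_id,
        content=content,
        concretizations=frozenset({attached.id}),
        produced_by=producing_process.id,
        first_concretized_at=attached.exists_during,
    )
    kb.add(ice)
    return ice


def check_conformance(
    a: RepresentationRecord, b: RepresentationRecord, kb: KnowledgeBase
) -> bool:
    """True iff both representations concretize the same ICE."""
    if a.id not in kb.representations:
        raise DeclarationError(a.id, "conformance check")
    if b.id not in kb.representations:
        raise DeclarationError(b.id, "conformance check")
    return a.concretizes is not None and a.concretizes == b.concretizes


def is_copy(representation: RepresentationRecord) -> bool:
    """Whether the representation was produced by copying (hearsay marker)."""
    return representation.copied_from is not None
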