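"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package internals: temporal
entailment is decided by enumerating concrete integer endpoint assignments,
and compound aboutness by exhaustive scans over the KB's collections.
"""

from __future__ import annotations

from rtdx.core_model import TemporalConstraint, Verdict


def _sat(rel: str, a: tuple[int, int], b: tuple[int, int]) -> bool:
    (s1, e1), (s2, e2) = a, b
    if rel == "equals":
        return s1 == s2 and e1 == e2
    if rel == "before":
        return e1 < s2
    if rel == "during":
        return s2 <= s1 and e1 <= e2
    if rel == "contains":
        return s1 <= s2 and e2 <= e1
    if rel == "starts":
        return s1 == s2 and e1 <= e2
    if rel == "ends":
        return e1 == e2 and s2 <= s1
    if rel == "overlaps":
        return s1 <= e2 and s2 <= e1
    raise ValueError(rel)


def oracle_entails(
    tids: list[str],
    constraints: list[TemporalConstraint],
    a: str,
    rel: str,
    b: str,
    timeline: int | None = None,
) -> Verdict | None:
    """Enumerate all endpoint assignments on an integer timeline.

    Returns HOLDS / FAILS / INDETERMINATE, or None when the constraint
    network itself has no model (inconsistent).  Only intervals connected to
    the query pair through constraints are enumerated — unconstrained
    intervals cannot influence the verdict.
    """
    # connected component(s) of a and b in the constraint graph
    adj: dict[str, set[str]] = {t: set() for t in tids}
    for c in constraints:
        adj.setdefault(c.subject, set()).add(c.object)
        adj.setdefault(c.object, set()).add(c.subject)
    keep: set[str] = set()
    stack = [a, b]
    while stack:
        t = stack.pop()
        if t in keep:
            continue
        keep.add(t)
        stack.extend(adj.get(t, ()))
    cons = [c for c in constraints if c.subject in keep and c.object in keep]
    if timeline is None:
        # 2k distinct values realize every relative endpoint configuration
        timeline = min(12, max(2 * len(keep), 2))
    # order intervals so each added one is constrained by an earlier one
    order: list[str] = []
    pending = set(keep)
    for seed_t in (a, b):
        if seed_t in pending:
            order.append(seed_t)
            pending.discard(seed_t)
    while pending:
        nxt = next(
            (t for t in sorted(pending) if any(n in order for n in adj.get(t, ()))),
            None,
        )
        if nxt is None:
            nxt = sorted(pending)[0]
        order.append(nxt)
        pending.discard(nxt)

    by_pair: dict[str, list[TemporalConstraint]] = {t: [] for t in keep}
    for c in cons:
        later = c.subject if order.index(c.subject) > order.index(c.object) else c.object
        by_pair[later].append(c)

    values = [(s, e) for s in range(timeline) for e in range(s, timeline)]
    touching: dict[str, list[TemporalConstraint]] = {t: [] for t in keep}
    for c in cons:
        touching[c.subject].append(c)
        if c.object != c.subject:
            touching[c.object].append(c)

    def consistent_with(t: str, val: tuple[int, int], asg: dict) -> bool:
        for c in touching[t]:
            other = c.object if c.subject == t else c.subject
            if other == t:
                if not _sat(c.relation, val, val):
                    return False
            elif other in asg:
                x = val if c.subject == t else asg[other]
                y = asg[other] if c.subject == t else val
                if not _sat(c.relation, x, y):
                    return False
        return True

    def search(want: bool) -> bool:
        """Is there a model whose (a, b) pair satisfies rel iff ``want``?

        First-solution backtracking with forward checking; the query pair is
        placed first in the variable order so its predicate prunes at depth 2.
        """
        asg: dict[str, tuple[int, int]] = {}

        def rec(i: int) -> bool:
            if i == len(order):
                return True
            t = order[i]
            for val in values:
                if not consistent_with(t, val, asg):
                    continue
                asg[t] = val
                if (t == a or t == b) and a in asg and b in asg:
                    if _sat(rel, asg[a], asg[b]) is not want:
                        del asg[t]
                        continue
                # forward check: every unassigned interval must keep a value
                ok = all(
                    any(consistent_with(u, v, asg) for v in values)
                    for u in order[i + 1 :]
                )
                if ok and rec(i + 1):
                    return True
                del asg[t]
            return False

        return rec(0)

    exists_r = search(True)
    exists_not = search(False)
    if not exists_r and not exists_not:
        return None
    if exists_r and not exists_not:
        return Verdict.HOLDS
    if exists_not and not exists_r:
        return Verdict.FAILS
    return Verdict.INDETERMINATE


def oracle_compound(content, kb) -> Verdict:
    """Exhaustive-scan re-derivation of the compound aboutness verdict."""
    particular_ids = (
        set(kb.particulars)
        | set(kb.configurations)
        | set(kb.representations)
        | set(kb.ices)
        | set(kb.processes)
        | set(kb.clinical_pictures)
        | set(kb.knowledge_aggregates)
    )
    refs_ok = True
    for mention in (content.asserted_organism, content.asserted_disease):
        if mention is not None and mention not in particular_ids:
            refs_ok = False
    u = kb.universals.get(content.asserted_type)
    if u is None or not u.exists_flag:
        refs_ok = False
    if content.asserted_organism is None or content.asserted_disease is None:
        refs_ok = False
    if not refs_ok:
        return Verdict.FAILS

    inheres = any(
        r.subject == content.asserted_disease
        and r.relation == "inheres_in"
        and r.object == content.asserted_organism
        for r in kb.relations
    )
    instantiates = any(
        i.particular == content.asserted_disease and i.universal == content.asserted_type
        for i in kb.instantiations
    )
    target = None
    for c in kb.configurations.values():  # enumerate all, match by identity
        if c.id == content.intended_target:
            target = c
    if not (inheres and instantiates and target is not None):
        return Verdict.FAILS
    if content.asserted_anchor not in kb.temporal_regions:
        return Verdict.INDETERMINATE
    verdict = oracle_entails(
        sorted(kb.temporal_regions),
        sorted(kb.temporal_constraints, key=lambda c: (c.subject, c.relation, c.object)),
        content.asserted_anchor,
        "overlaps",
        target.anchor,
    )
    assert verdict is not None, "oracle: inconsistent fixture network"
    return verdict
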