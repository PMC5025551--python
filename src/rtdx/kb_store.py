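"""In-memory store for one scenario's assertions.

A :class:`KnowledgeBase` is closed-world: it is taken to enumerate all
relevant particulars of its scenario, so existence checks are decidable.
Only temporal entailment is three-valued, because temporal regions are
identified by opaque ids whose relative placement may be unconstrained.

Temporal entailment works on a difference-constraint network over interval
endpoints.  Each of the seven named relations translates into a conjunction
of endpoint inequalities over closed integer intervals ``[s, e]`` (point
regions allowed, ``s == e``):

====================  =================================
``equals(a, b)``      ``sa = sb`` and ``ea = eb``
``before(a, b)``      ``ea < sb``
``during(a, b)``      ``sb <= sa`` and ``ea <= eb``
``contains(a, b)``    ``during(b, a)``
``starts(a, b)``      ``sa = sb`` and ``ea <= eb``
``ends(a, b)``        ``ea = eb`` and ``sb <= sa``
``overlaps(a, b)``    ``sa <= eb`` and ``sb <= ea``  (regions intersect)
====================  =================================

All are conjunctions of ``x - y <= c`` constraints, so the closure is the
all-pairs shortest-path matrix of the constraint graph: a conjunct is
entailed iff its implied bound is already at least as tight, and a relation
is refuted iff adding its conjuncts creates a negative cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core_model import (
    ClinicalPictureRecord,
    Configuration,
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
    TEMPORAL_RELATIONS,
    TYPE_TARGET_RELATIONS,
    Universal,
    Verdict,
    validate_record,
)
from .errors import DeclarationError, InconsistencyError

__all__ = ["KnowledgeBase", "WILDCARD"]

WILDCARD = "*"

_INF = float("inf")


def _edges_for(relation: str, a: str, b: str) -> list[tuple[str, str, int]]:
    """Endpoint constraints for ``relation(a, b)`` as (x, y, c) meaning x - y <= c."""
    sa, ea, sb, eb = ("s:" + a, "e:" + a, "s:" + b, "e:" + b)
    eq = lambda x, y: [(x, y, 0), (y, x, 0)]
    le = lambda x, y: [(x, y, 0)]
    lt = lambda x, y: [(x, y, -1)]
    if relation == "equals":
        return eq(sa, sb) + eq(ea, eb)
    if relation == "before":
        return lt(ea, sb)
    if relation == "during":
        return le(sb, sa) + le(ea, eb)
    if relation == "contains":
        return le(sa, sb) + le(eb, ea)
    if relation == "starts":
        return eq(sa, sb) + le(ea, eb)
    if relation == "ends":
        return eq(ea, eb) + le(sb, sa)
    if relation == "overlaps":
        return le(sa, eb) + le(sb, ea)
    raise ValueError(f"unknown temporal relation: {relation!r}")


class _TemporalNetwork:
    """Shortest-path closure over the endpoint constraint graph."""

    def __init__(self, tids: Iterable[str], constraints: Iterable[TemporalConstraint]):
        self.points: list[str] = []
        for t in tids:
            self.points.extend(("s:" + t, "e:" + t))
        self.index = {p: i for i, p in enumerate(self.points)}
        n = len(self.points)
        dist = [[0 if i == j else _INF for j in range(n)] for i in range(n)]

        def add_edge(x: str, y: str, c: int) -> None:
            # x - y <= c  ==>  edge y -> x of weight c
            i, j = self.index[y], self.index[x]
            if c < dist[i][j]:
                dist[i][j] = c

        for t in tids:
            add_edge("s:" + t, "e:" + t, 0)  # s <= e
        self._base_edges: list[tuple[str, str, int]] = []
        for c in constraints:
            for x, y, w in _edges_for(c.relation, c.subject, c.object):
                add_edge(x, y, w)
                self._base_edges.append((x, y, w))
        for k in range(n):
            dk = dist[k]
            for i in range(n):
                dik = dist[i][k]
                if dik == _INF:
                    continue
                di = dist[i]
                for j in range(n):
                    alt = dik + dk[j]
                    if alt < di[j]:
                        di[j] = alt
        self.dist = dist
        self._neg_node: Optional[int] = next(
            (i for i in range(n) if dist[i][i] < 0), None
        )

    def violating_cycle(self) -> list[str]:
        """One negative cycle's endpoint names, via Bellman-Ford predecessors
        (assumes the network is inconsistent)."""
        assert self._neg_node is not None
        n = len(self.points)
        edges = [("s:" + t, "e:" + t, 0) for t in {p[2:] for p in self.points}]
        edges += self._base_edges
        # x - y <= c: edge y -> x, weight c
        d = {p: 0 for p in self.points}
        pred: dict[str, str] = {}
        witness = None
        for _ in range(n):
            witness = None
            for x, y, c in edges:
                if d[y] + c < d[x]:
                    d[x] = d[y] + c
                    pred[x] = y
                    witness = x
            if witness is None:
                break
        assert witness is not None
        # walk back n steps to land inside the cycle, then trace it
        node = witness
        for _ in range(n):
            node = pred[node]
        cycle = [node]
        cur = pred[node]
        while cur != node:
            cycle.append(cur)
            cur = pred[cur]
        cycle.append(node)
        return list(reversed(cycle))

    @property
    def consistent(self) -> bool:
        return self._neg_node is None

    def _bound(self, x: str, y: str) -> float:
        """Tightest entailed bound on x - y."""
        return self.dist[self.index[y]][self.index[x]]

    def entails(self, a: str, relation: str, b: str) -> Verdict:
        if not self.consistent:
            raise InconsistencyError(self.violating_cycle())
        edges = _edges_for(relation, a, b)
        if all(self._bound(x, y) <= c for x, y, c in edges):
            return Verdict.HOLDS
        # Refuted iff base constraints plus the relation's conjuncts are
        # jointly unsatisfiable.  Check for a negative cycle that uses the
        # added edges, via a tiny Bellman-Ford restricted to them.
        if not self._satisfiable_with(edges):
            return Verdict.FAILS
        return Verdict.INDETERMINATE

    def _satisfiable_with(self, extra: list[tuple[str, str, int]]) -> bool:
        # Combine the closed base matrix with the extra edges; a negative
        # cycle can only arise through extra edges, so relax around them.
        involved = sorted({p for x, y, _ in extra for p in (x, y)}, key=self.index.get)
        idx = [self.index[p] for p in involved]
        m = len(idx)
        # d[i][j]: tightest path from involved[i] to involved[j] using base
        # closure plus extra edges among involved points.
        d = [[self.dist[idx[i]][idx[j]] for j in range(m)] for i in range(m)]
        pos = {p: i for i, p in enumerate(involved)}
        for x, y, c in extra:  # x - y <= c: edge y -> x
            i, j = pos[y], pos[x]
            if c < d[i][j]:
                d[i][j] = c
        for k in range(m):
            for i in range(m):
                for j in range(m):
                    alt = d[i][k] + d[k][j]
                    if alt < d[i][j]:
                        d[i][j] = alt
        return all(d[i][i] >= 0 for i in range(m))


_ASSERTION_TYPES = (
    TemporalConstraint,
    InstantiationAssertion,
    RelationAssertion,
    NegativeAssertion,
)


@dataclass
class KnowledgeBase:
    """All assertions of one scenario, with temporally indexed queries."""

    particulars: dict[str, Particular] = field(default_factory=dict)
    universals: dict[str, Universal] = field(default_factory=dict)
    temporal_regions: dict[str, TemporalRegion] = field(default_factory=dict)
    temporal_constraints: set[TemporalConstraint] = field(default_factory=set)
    instantiations: set[InstantiationAssertion] = field(default_factory=set)
    relations: set[RelationAssertion] = field(default_factory=set)
    negatives: set[NegativeAssertion] = field(default_factory=set)
    configurations: dict[str, Configuration] = field(default_factory=dict)
    representations: dict[str, RepresentationRecord] = field(default_factory=dict)
    ices: dict[str, ICERecord] = field(default_factory=dict)
    processes: dict[str, ProcessRecord] = field(default_factory=dict)
    clinical_pictures: dict[str, ClinicalPictureRecord] = field(default_factory=dict)
    knowledge_aggregates: dict[str, KnowledgeAggregate] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._network: Optional[_TemporalNetwork] = None

    # -- declarations -------------------------------------------------------

    def declared_ids(self) -> set[str]:
        return (
            set(self.particulars)
            | set(self.universals)
            | set(self.temporal_regions)
            | set(self.configurations)
            | set(self.representations)
            | set(self.ices)
            | set(self.processes)
            | set(self.clinical_pictures)
            | set(self.knowledge_aggregates)
        )

    def is_declared(self, identifier: str) -> bool:
        return identifier in self.declared_ids()

    def is_particular(self, identifier: str) -> bool:
        """Whether the id denotes any declared particular (configurations,
        ICEs, processes etc. are particulars too)."""
        return identifier in self.declared_ids() - set(self.universals) - set(self.temporal_regions)

    # -- mutation -----------------------------------------------------------

    def add(self, item) -> "KnowledgeBase":
        """Insert a declaration, record, or assertion; idempotent on duplicates.

        Assertion-level referents must already be declared.  Record-to-record
        references (an ICE's concretizations, a process's inputs) may be
        inserted in any order and are checked by :meth:`check_consistency`.
        """
        if isinstance(item, Particular):
            self.particulars[item.iui] = item
        elif isinstance(item, Universal):
            self.universals[item.uui] = item
        elif isinstance(item, TemporalRegion):
            self.temporal_regions[item.tid] = item
            self._network = None
        elif isinstance(item, TemporalConstraint):
            self._require_tid(item.subject)
            self._require_tid(item.object)
            self.temporal_constraints.add(item)
            self._network = None
        elif isinstance(item, InstantiationAssertion):
            self._require_particular(item.particular)
            self._require(item.universal, self.universals)
            self._require_tid(item.at)
            self.instantiations.add(item)
        elif isinstance(item, RelationAssertion):
            self._require_particular(item.subject)
            if item.relation in TYPE_TARGET_RELATIONS and item.object in self.universals:
                pass
            else:
                self._require_particular(item.object)
            self._require_tid(item.at)
            self.relations.add(item)
        elif isinstance(item, NegativeAssertion):
            self._require_particular(item.particular)
            self._require(item.universal, self.universals)
            self._require_tid(item.during)
            self.negatives.add(item)
        elif isinstance(item, Configuration):
            for m in item.members_particulars:
                self._require_particular(m)
            for m in item.members_universals:
                self._require(m, self.universals)
            self._require_tid(item.anchor)
            self.configurations[item.id] = item
        elif isinstance(item, RepresentationRecord):
            self.representations[item.id] = item
        elif isinstance(item, ICERecord):
            self.ices[item.id] = item
        elif isinstance(item, ProcessRecord):
            self.processes[item.id] = item
        elif isinstance(item, ClinicalPictureRecord):
            self.clinical_pictures[item.id] = item
        elif isinstance(item, KnowledgeAggregate):
            self.knowledge_aggregates[item.id] = item
        else:
            raise TypeError(f"cannot add {type(item).__name__} to a KnowledgeBase")
        return self

    def _require(self, identifier: str, table: dict) -> None:
        if identifier not in table:
            raise DeclarationError(identifier)

    def _require_tid(self, tid: str) -> None:
        if tid not in self.temporal_regions:
            raise DeclarationError(tid)

    def _require_particular(self, identifier: str) -> None:
        if not self.is_particular(identifier):
            raise DeclarationError(identifier)

    # -- queries ------------------------------------------------------------

    def query(
        self,
        subject: str = WILDCARD,
        relation: str = WILDCARD,
        object: str = WILDCARD,
        at: str = WILDCARD,
    ) -> frozenset[RelationAssertion]:
        """Exact-match filtering over relation and instantiation assertions;
        ``*`` matches anything.  Instantiations surface as ``instance_of``."""

        def match(s, r, o, t) -> bool:
            return (
                (subject == WILDCARD or s == subject)
                and (relation == WILDCARD or r == relation)
                and (object == WILDCARD or o == object)
                and (at == WILDCARD or t == at)
            )

        out = {a for a in self.relations if match(a.subject, a.relation, a.object, a.at)}
        out |= {
            RelationAssertion(a.particular, "instance_of", a.universal, a.at)
            for a in self.instantiations
            if match(a.particular, "instance_of", a.universal, a.at)
        }
        return frozenset(out)

    def entails_relation(self, subject: str, relation: str, object: str) -> bool:
        """Whether the KB asserts ``subject relation object`` at any time."""
        return bool(self.query(subject, relation, object))

    # -- temporal entailment -------------------------------------------------

    def _net(self) -> _TemporalNetwork:
        if self._network is None:
            self._network = _TemporalNetwork(
                sorted(self.temporal_regions), self.temporal_constraints
            )
        return self._network

    def entails_temporal(self, a: str, relation: str, b: str) -> Verdict:
        """Three-valued entailment of ``relation(a, b)`` under the closure of
        the declared constraints."""
        if relation not in TEMPORAL_RELATIONS:
            raise ValueError(f"unknown temporal relation: {relation!r}")
        self._require_tid(a)
        self._require_tid(b)
        return self._net().entails(a, relation, b)

    # -- consistency ---------------------------------------------------------

    def check_consistency(self) -> list[str]:
        """Report violations; an empty list means the KB is coherent.

        Covers (a) assertions temporally outside a relatum's existence
        interval, (b) positive/negative clashes over entailed-overlapping
        regions, (c) temporal network inconsistency, plus referential closure
        of record-to-record links and per-record invariants.
        """
        out: list[str] = []
        net_ok = True
        try:
            net = self._net()
            if not net.consistent:
                net_ok = False
                out.append("temporal inconsistency; cycle: " + " -> ".join(net.violating_cycle()))
        except InconsistencyError as exc:
            net_ok = False
            out.append(str(exc))

        def existence_of(identifier: str) -> Optional[str]:
            p = self.particulars.get(identifier)
            if p is not None and p.existence_interval in self.temporal_regions:
                return p.existence_interval
            return None

        if net_ok:
            for a in sorted(self.relations, key=lambda r: (r.subject, r.relation, r.object, r.at)):
                for relatum in (a.subject, a.object):
                    t_exist = existence_of(relatum)
                    if t_exist is None or a.at not in self.temporal_regions:
                        continue
                    if self.entails_temporal(a.at, "overlaps", t_exist) is Verdict.FAILS:
                        out.append(
                            f"assertion {a.subject} {a.relation} {a.object} at {a.at} "
                            f"falls outside the existence interval {t_exist} of {relatum}"
                        )
            # positive/negative clashes: overlap must be entailed, not merely
            # possible, because distinct tids may denote the same period
            for neg in sorted(self.negatives, key=lambda n: (n.particular, n.relation, n.universal, n.during)):
                for pos in self._positives_matching(neg):
                    if self.entails_temporal(pos.at, "overlaps", neg.during) is Verdict.HOLDS:
                        out.append(
                            f"clash: {pos.subject} {pos.relation} {pos.object} at {pos.at} "
                            f"contradicts lacks-{neg.relation}-to-{neg.universal} during {neg.during}"
                        )

        out.extend(self._closure_violations())
        for table in (
            self.particulars,
            self.universals,
            self.configurations,
            self.representations,
            self.ices,
            self.knowledge_aggregates,
            self.clinical_pictures,
            self.processes,
        ):
            for rec in table.values():
                out.extend(validate_record(rec))
        return out

    def _positives_matching(self, neg: NegativeAssertion) -> list[RelationAssertion]:
        """Positive assertions asserting the negated relation toward some
        instance of the negated universal (or the universal itself)."""
        instances = {i.particular for i in self.instantiations if i.universal == neg.universal}
        hits = []
        for a in self.relations:
            if a.subject != neg.particular or a.relation != neg.relation:
                continue
            if a.object == neg.universal or a.object in instances:
                hits.append(a)
        for i in self.instantiations:
            if neg.relation == "instance_of" and i.particular == neg.particular and i.universal == neg.universal:
                hits.append(RelationAssertion(i.particular, "instance_of", i.universal, i.at))
        return hits

    def _closure_violations(self) -> list[str]:
        out = []
        declared = self.declared_ids()

        def need(identifier: Optional[str], where: str) -> None:
            if identifier and identifier not in declared:
                out.append(f"{where}: undeclared reference {identifier}")

        for rep in self.representations.values():
            need(rep.bearer, f"representation {rep.id}")
            need(rep.concretizes, f"representation {rep.id}")
        for ice in self.ices.values():
            for c in ice.concretizations:
                need(c, f"ICE {ice.id}")
            need(ice.produced_by, f"ICE {ice.id}")
            # the intended target must be a declared configuration; the
            # organism/disease/type mentions are opaque and may dangle
            need(ice.content.intended_target, f"ICE {ice.id} content")
        for proc in self.processes.values():
            need(proc.agent, f"process {proc.id}")
            for x in proc.inputs | proc.outputs:
                need(x, f"process {proc.id}")
        for pic in self.clinical_pictures.values():
            need(pic.subject, f"clinical picture {pic.id}")
            for x in pic.inferred_from:
                need(x, f"clinical picture {pic.id}")
        for agg in self.knowledge_aggregates.values():
            need(agg.owner, f"aggregate {agg.id}")
            for u in agg.disease_types | agg.phenotype_types:
                need(u, f"aggregate {agg.id}")
        return out

    # -- convenience ---------------------------------------------------------

    def representation_of(self, rep_id: str) -> RepresentationRecord:
        try:
            return self.representations[rep_id]
        except KeyError:
            raise DeclarationError(rep_id, "representation lookup")

    def ice_of(self, ice_id: str) -> ICERecord:
        try:
            return self.ices[ice_id]
        except KeyError:
            raise DeclarationError(ice_id, "ICE lookup")

    def copy(self) -> "KnowledgeBase":
        """Independent shallow-structure copy (records are immutable)."""
        return KnowledgeBase(
            particulars=dict(self.particulars),
            universals=dict(self.universals),
            temporal_regions=dict(self.temporal_regions),
            temporal_constraints=set(self.temporal_constraints),
            instantiations=set(self.instantiations),
            relations=set(self.relations),
            negatives=set(self.negatives),
            configurations=dict(self.configurations),
            representations=dict(self.representations),
            ices=dict(self.ices),
            processes=dict(self.processes),
            clinical_pictures=dict(self.clinical_pictures),
            knowledge_aggregates=dict(self.knowledge_aggregates),
            metadata=dict(self.metadata),
        )

    def replace_ice(self, ice: ICERecord) -> None:
        self.ices[ice.id] = ice

    def mint_iui(self, prefix: str = "IUI-") -> str:
        """Smallest unused IUI above every declared numeric suffix."""
        used = {
            int(i.split("-")[1])
            for i in self.declared_ids()
            if i.startswith("IUI-") and i.split("-")[1].isdigit()
        }
        n = max(used, default=0) + 1
        return f"{prefix}{n}"
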