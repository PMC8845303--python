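"""E- and CD-equivalence: polynomial-delay class enumeration and per-class study.

An E-class assigns an event to every parasite node; a CD-class additionally
fixes the host of every non-switching node (switch targets are masked by a
``?`` placeholder).  Classes are enumerated directly from the reconciliation
graph — never by enumerating the reconciliations — by a top-down recursion
over *colors*: the projection of an OR+ label that the relation preserves
((p, e) for E; (p, h, e) with the host masked on switches for CD).  The
recursion keeps, for every partial class, the set of OR+ nodes that root a
solution subtree realizing it, which is what makes the "exactly once"
guarantee and the polynomial delay possible.  One generic code path serves
both relations, parameterized by the coloring.

The per-class operations (count, representative, within-class enumeration)
work by pruning the graph down to the OR+ nodes whose color corroborates the
class and re-running the generic graph algorithms on the result.

Per-node event supports (the share of optimal reconciliations assigning a
given event to a given node) are aggregated in a single pass from the number
of solution subtrees below each node and the number of ways to extend each
node to a start node; a decomposable AND/OR graph guarantees each solution
contains exactly one OR+ node per parasite node, so these through-counts
partition the solution space.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Optional

from .graph import EIDX, AndNode, OrNode, ReconGraph, count_solutions, enumerate_solutions
from .model import HOST_SWITCH, ProblemInstance, Reconciliation, TERMINAL

__all__ = [
    "ClassAssignment",
    "OpCounter",
    "node_color",
    "enumerate_classes",
    "prune_to_class",
    "class_info",
    "event_support",
    "EventSupport",
]

RELATIONS = ("E", "CD")


def node_color(label: tuple, relation: str) -> tuple:
    """Color of an OR+ label under a relation.

    E: ``(p, e)``.  CD: ``(p, h, e)``, with the host replaced by ``None``
    (rendered ``?``) when the event is a host-switch.
    """
    p, h, e = label
    if relation == "E":
        return (p, e)
    if relation == "CD":
        return (p, None, HOST_SWITCH) if e == HOST_SWITCH else (p, h, e)
    raise ValueError(f"unknown relation {relation!r}")


def _color_key(color: tuple) -> tuple:
    if len(color) == 2:
        p, e = color
        return (p, EIDX[e], -1)
    p, h, e = color
    return (p, EIDX[e], -1 if h is None else h)


@dataclass(frozen=True)
class ClassAssignment:
    """A total map from parasite nodes to the relation's per-node payload.

    E: ``p -> event``;  CD: ``p -> (event, host or None)`` where ``None``
    stands for the masked switch target ``?``.
    """

    relation: str
    items: tuple  # sorted tuple of (p, payload)

    @classmethod
    def from_colors(cls, relation: str, colors: dict) -> "ClassAssignment":
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        return cls(relation, tuple(sorted(colors.items())))

    @classmethod
    def from_reconciliation(cls, relation: str, phi: Reconciliation) -> "ClassAssignment":
        if relation == "E":
            items = tuple((p, e) for p, h, e in phi.triples())
        else:
            items = tuple(
                (p, (e, None if e == HOST_SWITCH else h)) for p, h, e in phi.triples()
            )
        return cls(relation, items)

    def as_dict(self) -> dict:
        return dict(self.items)

    def payload(self, p: int):
        return self.as_dict()[p]

    def to_jsonable(self, inst: ProblemInstance) -> dict:
        P, H = inst.parasite, inst.host
        if self.relation == "E":
            assignment = {P.name[p]: e for p, e in self.items}
        else:
            assignment = {
                P.name[p]: {"event": e, "host": "?" if h is None else H.name[h]}
                for p, (e, h) in self.items
            }
        return {"relation": self.relation, "assignment": assignment}


class OpCounter:
    """Counts the elementary grandchild-couple operations performed between
    consecutive class yields (used to check the polynomial-delay contract)."""

    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0

    def tick(self, k: int = 1) -> None:
        self.n += k


def _matches(label: tuple, relation: str, payload_by_p: dict) -> bool:
    p, h, e = label
    want = payload_by_p.get(p)
    if want is None:
        return False
    if relation == "E":
        return e == want
    we, wh = want
    if e != we:
        return False
    return wh is None if e == HOST_SWITCH else h == wh


def enumerate_classes(
    g: ReconGraph, relation: str = "E", op_counter: Optional[OpCounter] = None
) -> Iterator[tuple]:
    """Yield every equivalence class of the optimal reconciliations exactly
    once, as ``(ClassAssignment, roots)`` where ``roots`` is the frozenset of
    start nodes rooting a solution in that class.

    Requires a pruned graph (every node on at least one solution subtree),
    which :func:`reconspace.graph.build_graph` guarantees.  Lazy generators
    keep the delay between consecutive yields polynomial (O(m n^2) couple
    operations).
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    ops = op_counter or OpCounter()
    P = g.inst.parasite

    def enum(color: tuple, O: list) -> Iterator[tuple]:
        p = color[0]
        if P.is_leaf(p):
            yield {p: _payload(color)}, O
            return
        # group the grandchild couples of O by color couple
        groups: dict = {}
        for s in O:
            for a in s.ands:
                ops.tick()
                cc = (node_color(a.first.label, relation),
                      node_color(a.second.label, relation))
                groups.setdefault(cc, []).append((s, a.first, a.second))
        for cc in sorted(groups, key=lambda c: (_color_key(c[0]), _color_key(c[1]))):
            entries = groups[cc]
            O1 = _ordered({s1 for _, s1, _ in entries}, entries, 1)
            for T1, O1t in enum(cc[0], O1):
                sel1 = set(map(id, O1t))
                ops.tick(len(entries))
                O2 = _ordered({s2 for _, s1, s2 in entries if id(s1) in sel1},
                              entries, 2)
                for T2, O2t in enum(cc[1], O2):
                    sel2 = set(map(id, O2t))
                    ops.tick(len(entries))
                    roots = _dedup(s for s, s1, s2 in entries
                                   if id(s1) in sel1 and id(s2) in sel2)
                    yield {**T1, **T2, p: _payload(color)}, roots

    def _payload(color: tuple):
        return color[1] if relation == "E" else (color[2], color[1])

    def _ordered(allowed: set, entries: list, pos: int) -> list:
        seen: set = set()
        out: list = []
        for entry in entries:
            s = entry[pos]
            if s in allowed and id(s) not in seen:
                seen.add(id(s))
                out.append(s)
        return out

    def _dedup(it) -> list:
        seen: set = set()
        out: list = []
        for s in it:
            if id(s) not in seen:
                seen.add(id(s))
                out.append(s)
        return out

    groups: dict = {}
    for s in g.starts:
        groups.setdefault(node_color(s.label, relation), []).append(s)
    for color in sorted(groups, key=_color_key):
        for colors, roots in enum(color, groups[color]):
            yield (ClassAssignment.from_colors(relation, colors), frozenset(roots))


def prune_to_class(g: ReconGraph, cls: ClassAssignment) -> ReconGraph:
    """Subgraph whose solution subtrees are exactly the optimal
    reconciliations belonging to ``cls`` (empty graph if unrealized)."""
    P = g.inst.parasite
    payload = cls.as_dict()
    if set(payload) != set(P.postorder()):
        raise ValueError("class assignment must be total over the parasite tree")
    for p in P.leaves:
        want = payload[p]
        e = want if cls.relation == "E" else want[0]
        if e != TERMINAL:
            raise ValueError(f"leaf {P.name[p]!r} must carry the terminal event")

    kept: dict = {}
    for node in g.bottom_up():
        if not _matches(node.label, cls.relation, payload):
            continue
        if node.goal:
            kept[node.label] = OrNode(node.label, node.ivalue)
            continue
        copy = OrNode(node.label, node.ivalue)
        for a in node.ands:
            c1 = kept.get(a.first.label)
            c2 = kept.get(a.second.label)
            if c1 is not None and c2 is not None:
                copy.ands.append(AndNode(c1, c2))
        if copy.ands:
            kept[node.label] = copy

    starts = [kept[s.label] for s in g.starts if s.label in kept]
    reach: dict = {}
    stack = list(starts)
    while stack:
        s = stack.pop()
        if s.label in reach:
            continue
        reach[s.label] = s
        for a in s.ands:
            stack.extend((a.first, a.second))
    return ReconGraph(g.inst, reach, starts, g.scale, g.opt_ivalue)


def class_info(g: ReconGraph, cls: ClassAssignment, mode: str = "count"):
    """Count / pick a representative of / enumerate one equivalence class."""
    sub = prune_to_class(g, cls)
    if mode == "count":
        return count_solutions(sub)
    if not sub.starts:
        raise ValueError("empty class")
    if mode == "representative":
        return next(enumerate_solutions(sub, limit=1))
    if mode == "enumerate":
        return enumerate_solutions(sub)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EventSupport:
    """Per-node event counts over the optimal solution space."""

    counts: dict  # p -> {event: exact count}
    total: int

    def proportions(self) -> dict:
        return {
            p: {e: Fraction(c, self.total) for e, c in by_e.items()}
            for p, by_e in self.counts.items()
        }

    @property
    def consistent_nodes(self) -> dict:
        """Nodes whose event is the same in every optimal reconciliation."""
        return {
            p: next(iter(by_e))
            for p, by_e in self.counts.items()
            if len(by_e) == 1
        }


def event_support(g: ReconGraph) -> EventSupport:
    """Support of each (parasite node, event) pair: the exact number of
    optimal reconciliations assigning that event to that node."""
    below = g.solution_counts()
    above: dict = {s: 0 for s in g.nodes.values()}
    for s in g.starts:
        above[s] += 1
    for node in g.top_down():
        up = above[node]
        if up == 0:
            continue
        for a in node.ands:
            above[a.first] += up * below[a.second]
            above[a.second] += up * below[a.first]
    counts: dict = {}
    for node in g.nodes.values():
        p, h, e = node.label
        through = above[node] * below[node]
        if through:
            by_e = counts.setdefault(p, {})
            by_e[e] = by_e.get(e, 0) + through
    total = sum(below[s] for s in g.starts)
    return EventSupport(counts=counts, total=total)
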