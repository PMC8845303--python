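"""Event-vector (V-)equivalence machinery.

For every OR+ node s of the reconciliation graph, EV(s) is the set of event
vectors achievable by the solution subtrees rooted at s; for a goal node it
is {(0,0,0,0)}, and for an OR node it is the union, over its grandchild
couples, of the Cartesian sums of the children's EV sets shifted by the
couple's loss contribution and the node's own event.  The union of EV over
the start nodes is exactly the set of event vectors of the optimal
reconciliations.  In counting mode each vector also carries the exact number
of solution subtrees realizing it (convolution of the child counts), which
yields the solution-space proportions directly.

Cartesian sums are computed naively with hash-map deduplication; the number
of distinct vectors per node is polynomially bounded (the first three
components sum to the number of internal parasite nodes and the loss
component is bounded by tree size times diameter).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterator, Optional

from .model import (
    COSPECIATION,
    DUPLICATION,
    EVENT_DELTA,
    HOST_SWITCH,
    Reconciliation,
)
from .graph import OrNode, ReconGraph
from .trees import TreeIndex

__all__ = [
    "EVTable",
    "couple_loss",
    "compute_ev",
    "list_vector_classes",
    "backtrack_representative",
    "enumerate_in_vector_class",
    "vector_frequencies",
]

ZERO = (0, 0, 0, 0)


def couple_loss(hidx: TreeIndex, h: int, e: str, h1: int, h2: int) -> int:
    """Loss contribution of a grandchild couple under its parent's event."""
    dep = hidx.depth
    if e == COSPECIATION:
        return dep[h1] + dep[h2] - 2 * dep[h] - 2
    if e == DUPLICATION:
        return dep[h1] + dep[h2] - 2 * dep[h]
    if e == HOST_SWITCH:
        # arcs are charged on the descendant side; the switcher lands free
        desc = h1 if hidx.is_ancestor_or_self(h, h1) else h2
        return dep[desc] - dep[h]
    raise ValueError(f"no loss contribution for event {e!r}")


class EVTable:
    """Per-OR+-node achievable event vectors, optionally with solution counts.

    ``table[node]`` is ``{vector: count}`` in counting mode, else a ``set``.
    """

    def __init__(self, table: dict, with_counts: bool):
        self.table = table
        self.with_counts = with_counts

    def vectors(self, node: OrNode) -> set:
        entry = self.table[node]
        return set(entry)

    def __getitem__(self, node: OrNode):
        return self.table[node]


def compute_ev(g: ReconGraph, with_counts: bool = True) -> EVTable:
    """Bottom-up EV computation over the pruned graph."""
    hidx = g.inst.hidx
    table: dict = {}
    for node in g.bottom_up():
        p, h, e = node.label
        if node.goal:
            table[node] = {ZERO: 1} if with_counts else {ZERO}
            continue
        delta = EVENT_DELTA[e]
        acc: dict = {} if with_counts else set()
        for a in node.ands:
            xi = couple_loss(hidx, h, e, a.first.label[1], a.second.label[1])
            shift = (delta[0], delta[1], delta[2], delta[3] + xi)
            ev1, ev2 = table[a.first], table[a.second]
            if with_counts:
                for u, cu in ev1.items():
                    for w, cw in ev2.items():
                        v = (u[0] + w[0] + shift[0], u[1] + w[1] + shift[1],
                             u[2] + w[2] + shift[2], u[3] + w[3] + shift[3])
                        acc[v] = acc.get(v, 0) + cu * cw
            else:
                for u in ev1:
                    for w in ev2:
                        acc.add((u[0] + w[0] + shift[0], u[1] + w[1] + shift[1],
                                 u[2] + w[2] + shift[2], u[3] + w[3] + shift[3]))
        table[node] = acc
    return EVTable(table, with_counts)


def list_vector_classes(g: ReconGraph, ev: Optional[EVTable] = None) -> set:
    """All event vectors realized by optimal reconciliations."""
    if ev is None:
        ev = compute_ev(g, with_counts=False)
    out: set = set()
    for s in g.starts:
        out |= ev.vectors(s)
    return out


def _couple_splits(ev: EVTable, hidx: TreeIndex, node: OrNode, v: tuple):
    """Yield ``(and_node, u, w)`` decompositions of target vector v, in
    canonical order."""
    p, h, e = node.label
    delta = EVENT_DELTA[e]
    for a in node.ands:
        xi = couple_loss(hidx, h, e, a.first.label[1], a.second.label[1])
        base = (v[0] - delta[0], v[1] - delta[1], v[2] - delta[2],
                v[3] - delta[3] - xi)
        ev2 = ev[a.second]
        for u in sorted(ev[a.first]):
            w = (base[0] - u[0], base[1] - u[1], base[2] - u[2], base[3] - u[3])
            if min(w) < 0:
                continue
            if w in ev2:
                yield a, u, w


def backtrack_representative(g: ReconGraph, ev: EVTable, s: OrNode, v: tuple) -> Reconciliation:
    """One optimal reconciliation below start node ``s`` with event vector ``v``.

    Deterministic: always the first decomposition in canonical order.
    """
    if v not in ev[s]:
        raise ValueError(f"vector {v} not achievable from node {s.label}")
    hidx = g.inst.hidx
    out: dict = {}

    def rec(node: OrNode, vec: tuple) -> None:
        p, h, e = node.label
        out[p] = (h, e)
        if node.goal:
            return
        for a, u, w in _couple_splits(ev, hidx, node, vec):
            rec(a.first, u)
            rec(a.second, w)
            return
        raise AssertionError("EV table inconsistent with graph")

    rec(s, v)
    return Reconciliation.from_dict(out)


def enumerate_in_vector_class(
    g: ReconGraph, v: tuple, ev: Optional[EVTable] = None
) -> Iterator[Reconciliation]:
    """All optimal reconciliations with event vector ``v``, each exactly once
    (the all-branches variant of the backtrack)."""
    if ev is None:
        ev = compute_ev(g, with_counts=False)
    hidx = g.inst.hidx

    def rec(node: OrNode, vec: tuple) -> Iterator[tuple]:
        if node.goal:
            yield (node.label,)
            return
        for a, u, w in _couple_splits(ev, hidx, node, vec):
            for left in rec(a.first, u):
                for right in rec(a.second, w):
                    yield left + right + (node.label,)

    found = False
    for s in g.starts:
        if v in ev.vectors(s):
            found = True
            for labels in rec(s, v):
                yield Reconciliation.from_dict({p: (h, e) for p, h, e in labels})
    if not found:
        raise ValueError(f"unknown event vector {v}")


def vector_frequencies(g: ReconGraph, ev: Optional[EVTable] = None) -> dict:
    """``{vector: exact proportion of the solution space}`` (sums to 1)."""
    if ev is None or not ev.with_counts:
        ev = compute_ev(g, with_counts=True)
    counts: dict = {}
    for s in g.starts:
        for v, c in ev[s].items():
            counts[v] = counts.get(v, 0) + c
    total = sum(counts.values())
    return {v: Fraction(c, total) for v, c in counts.items()}


def vector_counts(g: ReconGraph, ev: Optional[EVTable] = None) -> dict:
    """``{vector: exact number of optimal reconciliations}``."""
    if ev is None or not ev.with_counts:
        ev = compute_ev(g, with_counts=True)
    counts: dict = {}
    for s in g.starts:
        for v, c in ev[s].items():
            counts[v] = counts.get(v, 0) + c
    return counts
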