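"""The reconciliation graph: a pruned acyclic decomposable AND/OR graph.

Every OR+ node is labeled by a DP cell ``(p, h, e)`` — "the parasite subtree
rooted at p is reconciled with p mapped to host h under event e" — and every
AND node joins one choice of cells for the two parasite children.  After
pruning, the solution subtrees of the graph (one start node; one AND child
per OR node; both children of every AND node) correspond bijectively to the
optimal reconciliations of the instance.

Construction strategy
---------------------
The textbook construction materializes all O(n^3 m) AND nodes and then
prunes.  Here the cell values f(p, h, e) are computed first in O(nm) time by
exploiting that, for a fixed cell, the objective separates into independent
minimizations over the two child hosts (subtree minima handle the
loss-per-arc terms; an "outside" pass handles the incomparable hosts a
switching child may jump to).  Only AND nodes whose value equals their
parent OR's value — and that are reachable from a surviving start cell — are
then materialized top-down.  This yields exactly the pruned graph: an AND
node survives the classical arc/root pruning plus dead-node sweep if and
only if it is value-achieving and reachable, so every materialized node lies
on at least one solution subtree.

Arithmetic is exact: rational costs are rescaled to integers (values are
stored as scaled ints, exposed as ``Fraction``), and solution counts use
Python's unbounded integers.
"""

from __future__ import annotations

from fractions import Fraction
from math import lcm
from typing import Iterator, Optional, Sequence

import numpy as np

from .model import (
    COSPECIATION,
    DUPLICATION,
    EVENTS,
    HOST_SWITCH,
    InfeasibleError,
    ProblemInstance,
    Reconciliation,
    TERMINAL,
)

__all__ = [
    "OrNode",
    "AndNode",
    "ReconGraph",
    "build_graph",
    "optimal_cost",
    "count_solutions",
    "enumerate_solutions",
    "start_subgraph",
]

EIDX = {e: i for i, e in enumerate(EVENTS)}  # C=0 D=1 S=2 T=3

INF = 1 << 60
BIG = 1 << 59  # anything at or above this is treated as unreachable


def _add(*vals: int) -> int:
    t = 0
    for v in vals:
        if v >= BIG:
            return INF
        t += v
    return t if t < BIG else INF


class AndNode:
    """One joint choice of child cells; children are an *ordered* couple
    matching the parasite children's order."""

    __slots__ = ("first", "second")

    def __init__(self, first: "OrNode", second: "OrNode"):
        self.first = first
        self.second = second

    @property
    def couple(self) -> tuple:
        return (self.first, self.second)


class OrNode:
    __slots__ = ("label", "ands", "ivalue")

    def __init__(self, label: tuple, ivalue: int):
        self.label = label  # (p, h, e)
        self.ands: list = []  # AndNode children, canonical order
        self.ivalue = ivalue  # value on the scaled-integer cost scale

    @property
    def goal(self) -> bool:
        return self.label[2] == TERMINAL

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"OrNode{self.label}"


def _sort_key(label: tuple) -> tuple:
    p, h, e = label
    return (p, h, EIDX[e])


class ReconGraph:
    """Pruned reconciliation graph; also used for class-restricted subgraphs."""

    def __init__(self, inst: ProblemInstance, nodes: dict, starts: list, scale: int,
                 opt_ivalue: int):
        self.inst = inst
        #: label -> OrNode, in bottom-up (child-cells-first) canonical order
        self.nodes = dict(sorted(nodes.items(), key=lambda kv: _sort_key(kv[0])))
        self.starts = sorted(starts, key=lambda s: _sort_key(s.label))
        self.scale = scale
        self.opt_ivalue = opt_ivalue

    @property
    def optimal_cost(self) -> Fraction:
        return Fraction(self.opt_ivalue, self.scale)

    def value_of(self, node: OrNode) -> Fraction:
        return Fraction(node.ivalue, self.scale)

    def bottom_up(self) -> Iterator[OrNode]:
        return iter(self.nodes.values())

    def top_down(self) -> Iterator[OrNode]:
        return reversed(list(self.nodes.values()))

    def solution_counts(self) -> dict:
        """Number of solution subtrees rooted at each node (exact big ints)."""
        below: dict = {}
        for s in self.bottom_up():
            if s.goal:
                below[s] = 1
            else:
                below[s] = sum(below[a.first] * below[a.second] for a in s.ands)
        return below

    def audit(self) -> None:
        """Structural sanity checks (bipartite DAG shape, degrees, label
        bijection, decomposability); raises AssertionError on violation."""
        seen_and = set()
        for s in self.nodes.values():
            assert self.nodes[s.label] is s, "label/node bijection broken"
            if s.goal:
                assert not s.ands
            else:
                assert s.ands, f"OR node {s.label} has no AND child"
            for a in s.ands:
                assert id(a) not in seen_and, "AND node with in-degree > 1"
                seen_and.add(id(a))
                assert a.first.label in self.nodes and a.second.label in self.nodes
        # decomposability: children of an AND reach disjoint node sets
        reach: dict = {}
        for s in self.bottom_up():
            r = {s.label}
            for a in s.ands:
                assert not (reach[a.first.label] & reach[a.second.label]), \
                    f"AND under {s.label} not decomposable"
                r |= reach[a.first.label]
                r |= reach[a.second.label]
            reach[s.label] = r
        # every node reachable from a start node
        live: set = set()
        stack = [s.label for s in self.starts]
        while stack:
            lab = stack.pop()
            if lab in live:
                continue
            live.add(lab)
            for a in self.nodes[lab].ands:
                stack.extend((a.first.label, a.second.label))
        assert live == set(self.nodes), "dead nodes present"

    def to_jsonl(self) -> str:
        """Debug dump: one JSON record per node."""
        import json

        P, H = self.inst.parasite, self.inst.host
        out = []
        ids = {s: i for i, s in enumerate(self.bottom_up())}
        k = len(ids)
        for s, i in ids.items():
            p, h, e = s.label
            rec = {"id": i, "kind": "or", "label": [P.name[p], H.name[h], e],
                   "value": str(self.value_of(s)), "children": []}
            for a in s.ands:
                rec["children"].append(k)
                out.append(json.dumps({"id": k, "kind": "and",
                                       "children": [ids[a.first], ids[a.second]]}))
                k += 1
            out.append(json.dumps(rec))
        return "\n".join(out)


def _host_arrays(inst: ProblemInstance):
    H, hidx = inst.host, inst.hidx
    n = len(H)
    depth = np.asarray(hidx.depth, dtype=np.int64)
    tin = np.asarray(hidx.tin, dtype=np.int64)
    tout = np.asarray(hidx.tout, dtype=np.int64)
    # anc[u, v] == u is an ancestor of v, self included
    anc = (tin[:, None] <= tin[None, :]) & (tin[None, :] < tout[:, None])
    return n, depth, anc


def _subtree_minima(tree, vals: Sequence) -> list:
    """Per-node minimum of ``vals`` over the node's subtree (self included)."""
    out = [INF] * len(tree)
    for v in tree.postorder():
        m = vals[v]
        if not tree.is_leaf(v):
            a, b = tree.children[v]
            m = min(m, out[a], out[b])
        out[v] = m
    return out


def _outside_minima(tree, dmin: Sequence) -> list:
    """Per-node minimum of the underlying values over nodes *incomparable* to it."""
    out = [INF] * len(tree)
    for v in reversed(range(len(tree))):  # reverse postorder = parents first
        if tree.is_leaf(v):
            continue
        a, b = tree.children[v]
        out[a] = min(out[v], dmin[b])
        out[b] = min(out[v], dmin[a])
    return out


def build_graph(inst: ProblemInstance) -> ReconGraph:
    """Build the pruned reconciliation graph of an instance.

    Raises :class:`InfeasibleError` if no valid reconciliation exists.
    """
    P, H = inst.parasite, inst.host
    n, depth, anc = _host_arrays(inst)
    scale = lcm(*(c.denominator for c in inst.costs))
    cC, cD, cS, cL = (int(c * scale) for c in inst.costs)

    # ---- phase 1: cell values, bottom-up over the parasite tree -------------
    # f[p] is an (n, 4) array of scaled-integer values (INF = unreachable).
    f: dict = {}
    aux: dict = {}  # p -> per-child precomputed minima used again in phase 2
    for p in P.postorder():
        fp = np.full((n, 4), INF, dtype=np.int64)
        if P.is_leaf(p):
            fp[inst.sigma[p], EIDX[TERMINAL]] = 0
            f[p] = fp
            continue
        p1, p2 = P.children[p]
        F1 = f[p1].min(axis=1)
        F2 = f[p2].min(axis=1)
        # A_i(x) = F_i(x) + c(L)*depth(x): minimizing A over a subtree of h
        # accounts for the per-arc loss charge below h in one shot.
        A1 = np.where(F1 >= BIG, INF, F1 + cL * depth)
        A2 = np.where(F2 >= BIG, INF, F2 + cL * depth)
        dA1 = _subtree_minima(H, A1.tolist())
        dA2 = _subtree_minima(H, A2.tolist())
        dF1 = _subtree_minima(H, F1.tolist())
        dF2 = _subtree_minima(H, F2.tolist())
        out1 = _outside_minima(H, dF1)
        out2 = _outside_minima(H, dF2)
        dep = inst.hidx.depth
        for h in H.postorder():
            if not H.is_leaf(h):
                hl, hr = H.children[h]
                fp[h, EIDX[COSPECIATION]] = _add(
                    cC, -2 * cL * (dep[h] + 1),
                    min(_add(dA1[hl], dA2[hr]), _add(dA1[hr], dA2[hl])))
            # duplication: both child hosts inside the subtree of h, minus
            # the cospeciation pairs; regions {h}xsub, subx{h}, sub(hl)^2, sub(hr)^2
            cand = min(_add(int(A1[h]), dA2[h]), _add(dA1[h], int(A2[h])))
            if not H.is_leaf(h):
                cand = min(cand, _add(dA1[hl], dA2[hl]), _add(dA1[hr], dA2[hr]))
            fp[h, EIDX[DUPLICATION]] = _add(cD, -2 * cL * dep[h], cand)
            fp[h, EIDX[HOST_SWITCH]] = _add(
                cS, min(_add(dA1[h], -cL * dep[h], out2[h]),
                        _add(dA2[h], -cL * dep[h], out1[h])))
        f[p] = fp
        aux[p] = (F1, F2)

    root = P.root
    opt = int(f[root].min())
    if opt >= BIG:
        raise InfeasibleError("instance admits no valid reconciliation")

    # ---- phase 2: materialize value-achieving cells top-down ----------------
    nodes: dict = {}
    idx_to_event = EVENTS

    def get_node(label: tuple, ivalue: int) -> OrNode:
        node = nodes.get(label)
        if node is None:
            node = OrNode(label, ivalue)
            nodes[label] = node
            _expand(node)
        return node

    def _expand(node: OrNode) -> None:
        p, h, e = node.label
        if P.is_leaf(p):
            return
        p1, p2 = P.children[p]
        F1, F2 = aux[p]
        fin1 = F1 < BIG
        fin2 = F2 < BIG
        dd = depth - depth[h]
        desc = anc[h]  # descendants of h, self included
        above = anc[:, h]
        incomp = ~(desc | above)
        ei = EIDX[e]
        pairs: list = []
        if e == COSPECIATION:
            if H.is_leaf(h):
                return
            hl, hr = H.children[h]
            for x, y in ((hl, hr), (hr, hl)):
                mask = np.outer(anc[x] & fin1, anc[y] & fin2)
                if not mask.any():
                    continue
                tot = (F1[:, None] + F2[None, :]
                       + cL * (dd[:, None] + dd[None, :] - 2) + cC)
                pairs.extend(map(tuple, np.argwhere(mask & (tot == node.ivalue))))
        elif e == DUPLICATION:
            mask = np.outer(desc & fin1, desc & fin2)
            if not H.is_leaf(h):
                hl, hr = H.children[h]
                cmask = np.outer(anc[hl], anc[hr]) | np.outer(anc[hr], anc[hl])
                mask &= ~cmask
            tot = F1[:, None] + F2[None, :] + cL * (dd[:, None] + dd[None, :]) + cD
            pairs.extend(map(tuple, np.argwhere(mask & (tot == node.ivalue))))
        else:  # HOST_SWITCH: loss arcs are charged on the descendant side only
            maskA = np.outer(incomp & fin1, desc & fin2)
            maskB = np.outer(desc & fin1, incomp & fin2)
            if maskA.any():
                tot = F1[:, None] + F2[None, :] + cL * dd[None, :] + cS
                pairs.extend(map(tuple, np.argwhere(maskA & (tot == node.ivalue))))
            if maskB.any():
                tot = F1[:, None] + F2[None, :] + cL * dd[:, None] + cS
                pairs.extend(map(tuple, np.argwhere(maskB & (tot == node.ivalue))))
        # canonical AND order: (h1, e1, h2, e2)
        expanded = []
        for h1, h2 in pairs:
            h1, h2 = int(h1), int(h2)
            e1s = [i for i in range(4) if f[p1][h1, i] == F1[h1]]
            e2s = [i for i in range(4) if f[p2][h2, i] == F2[h2]]
            for i1 in e1s:
                for i2 in e2s:
                    expanded.append((h1, i1, h2, i2))
        for h1, i1, h2, i2 in sorted(expanded):
            c1 = get_node((p1, h1, idx_to_event[i1]), int(F1[h1]))
            c2 = get_node((p2, h2, idx_to_event[i2]), int(F2[h2]))
            node.ands.append(AndNode(c1, c2))

    starts = []
    froot = f[root]
    for h in H.postorder():
        for i, e in enumerate(EVENTS):
            if froot[h, i] == opt:
                starts.append(get_node((root, h, e), opt))

    return ReconGraph(inst, nodes, starts, scale, opt)


# ---------------------------------------------------------------------------
# operations on a (possibly restricted) graph


def optimal_cost(g: ReconGraph) -> Fraction:
    return g.optimal_cost


def count_solutions(g: ReconGraph) -> int:
    """|T(G)|, exactly, with unbounded integers."""
    below = g.solution_counts()
    return sum(below[s] for s in g.starts)


def _subtree_stream(node: OrNode) -> Iterator[tuple]:
    """Yield each solution subtree below ``node`` as a tuple of OR labels."""
    if node.goal:
        yield (node.label,)
        return
    for a in node.ands:
        for left in _subtree_stream(a.first):
            for right in _subtree_stream(a.second):
                yield left + right + (node.label,)


def enumerate_solutions(g: ReconGraph, limit: Optional[int] = None) -> Iterator[Reconciliation]:
    """Stream the optimal reconciliations, each exactly once, deterministically.

    Delay between consecutive outputs is O(m) graph operations (the standard
    nested-generator traversal of an ad-AND/OR graph).
    """
    emitted = 0
    for s in g.starts:
        for labels in _subtree_stream(s):
            if limit is not None and emitted >= limit:
                return
            yield Reconciliation.from_dict({p: (h, e) for p, h, e in labels})
            emitted += 1


def start_subgraph(g: ReconGraph, O: Sequence) -> ReconGraph:
    """G/O: the view of ``g`` whose start set is ``O`` (node objects shared)."""
    O = list(O)
    if not O:
        raise ValueError("start set must be nonempty")
    for s in O:
        if not isinstance(s, OrNode):
            raise TypeError("start set must contain OR+ nodes")
    reach: dict = {}
    stack = list(O)
    while stack:
        s = stack.pop()
        if s.label in reach:
            continue
        reach[s.label] = s
        for a in s.ands:
            stack.extend((a.first, a.second))
    return ReconGraph(g.inst, reach, list(O), g.scale,
                      min(s.ivalue for s in O))
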