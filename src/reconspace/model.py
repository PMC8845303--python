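"""The event-based parsimony model of host/parasite reconciliation.

A reconciliation maps every parasite node to a host node.  Leaves follow the
observed associations sigma and carry the terminal event T; each internal
parasite node, from the hosts of itself and its two children, is classified
as a cospeciation (C), duplication (D) or host-switch (S), and additionally
contributes a nonnegative number of losses (L) measured as arc distances in
the host tree.  The cost of a reconciliation is the dot product of its event
vector (#C, #D, #S, #L) with a user-supplied cost vector.

Costs are exact rationals throughout: float ties would silently change the
optimal set and hence every downstream count.

This module also houses the brute-force oracle (:func:`enumerate_all_valid`,
:func:`brute_force_optimal`) which enumerates reconciliations by exhaustive
assignment, with none of the graph machinery — it is the ground truth the
rest of the package is tested against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Optional, Sequence

from .trees import MappingError, PhyloTree, TreeIndex, index_tree

__all__ = [
    "EVENTS",
    "COSPECIATION",
    "DUPLICATION",
    "HOST_SWITCH",
    "TERMINAL",
    "CostVector",
    "ProblemInstance",
    "Reconciliation",
    "InfeasibleError",
    "parse_cost_vector",
    "classify_event",
    "loss_contribution",
    "validate_reconciliation",
    "event_vector",
    "reconciliation_cost",
    "enumerate_all_valid",
    "brute_force_optimal",
]

COSPECIATION = "C"
DUPLICATION = "D"
HOST_SWITCH = "S"
TERMINAL = "T"
#: canonical event order (also the tie-break order everywhere)
EVENTS = (COSPECIATION, DUPLICATION, HOST_SWITCH, TERMINAL)

#: event -> increment of the first three event-vector components
EVENT_DELTA = {
    COSPECIATION: (1, 0, 0, 0),
    DUPLICATION: (0, 1, 0, 0),
    HOST_SWITCH: (0, 0, 1, 0),
}

CostVector = tuple  # tuple[Fraction, Fraction, Fraction, Fraction] — (C, D, S, L)


class InfeasibleError(RuntimeError):
    """No valid reconciliation exists for the instance."""


def parse_cost_vector(text: str) -> CostVector:
    """Parse ``"c(C),c(D),c(S),c(L)"`` decimal strings into exact rationals."""
    parts = [p.strip() for p in text.split(",")]
    if len(parts) != 4:
        raise ValueError(f"cost vector needs 4 comma-separated numbers, got {text!r}")
    try:
        # U+2212 minus occasionally sneaks in from copy-pasted tables
        return tuple(Fraction(p.replace("−", "-")) for p in parts)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"bad cost vector {text!r}: {exc}") from exc


@dataclass
class ProblemInstance:
    """An instance (H, P, sigma, cost vector) with prebuilt tree indices."""

    host: PhyloTree
    parasite: PhyloTree
    sigma: dict  # parasite leaf id -> host leaf id
    costs: CostVector
    hidx: TreeIndex = field(init=False)
    pidx: TreeIndex = field(init=False)

    def __post_init__(self) -> None:
        self.costs = tuple(Fraction(c) for c in self.costs)
        if len(self.costs) != 4:
            raise ValueError("cost vector must have exactly four components")
        self.hidx = index_tree(self.host)
        self.pidx = index_tree(self.parasite)
        for p in self.parasite.leaves:
            h = self.sigma.get(p)
            if h is None:
                raise MappingError(f"parasite leaf {self.parasite.name[p]!r} unmapped")
            if not (0 <= h < len(self.host)) or not self.host.is_leaf(h):
                raise MappingError(
                    f"image of {self.parasite.name[p]!r} is not a host leaf"
                )

    def with_costs(self, costs: Sequence) -> "ProblemInstance":
        return ProblemInstance(self.host, self.parasite, self.sigma, tuple(costs))

    @property
    def internal_parasites(self) -> list:
        return [p for p in self.parasite.postorder() if not self.parasite.is_leaf(p)]


@dataclass(frozen=True)
class Reconciliation:
    """phi plus induced events, as one ``(host, event)`` pair per parasite node.

    The canonical form — triples sorted by parasite postorder index — makes
    serialization deterministic and set-equality tests trivial.
    """

    mapping: tuple  # tuple[tuple[int, int, str], ...] sorted by parasite id

    @classmethod
    def from_dict(cls, d: dict) -> "Reconciliation":
        return cls(tuple((p, h, e) for p, (h, e) in sorted(d.items())))

    def as_dict(self) -> dict:
        return {p: (h, e) for p, h, e in self.mapping}

    def host_of(self, p: int) -> int:
        return self.mapping[p][1]

    def event_of(self, p: int) -> str:
        return self.mapping[p][2]

    def triples(self) -> tuple:
        return self.mapping

    def to_tsv(self, inst: ProblemInstance, header: bool = True) -> str:
        lines = []
        if header:
            lines.append("parasite_node\thost_node\tevent\tlosses")
        for p, h, e in self.mapping:
            loss = 0
            if e != TERMINAL:
                p1, p2 = inst.parasite.children[p]
                loss = loss_contribution(inst.hidx, h, self.host_of(p1), self.host_of(p2))
            lines.append(
                f"{inst.parasite.name[p]}\t{inst.host.name[h]}\t{e}\t{loss}"
            )
        return "\n".join(lines)


def classify_event(hidx: TreeIndex, h: int, h1: int, h2: int) -> Optional[str]:
    """Event induced at a parasite node mapped to ``h`` whose children map to ``h1, h2``.

    The cases are tested in an order that makes them mutually exclusive:
    host-switch (exactly one child's host incomparable to ``h``, the other a
    descendant of ``h``, self included), then cospeciation (``h`` is the
    strict meet of two incomparable child hosts), then duplication as the
    catch-all when both child hosts descend from ``h``.  Returns ``None``
    when no event is valid (e.g. both children incomparable to ``h``).
    """
    desc1 = hidx.is_ancestor_or_self(h, h1)
    desc2 = hidx.is_ancestor_or_self(h, h2)
    inc1 = not desc1 and not hidx.is_ancestor_or_self(h1, h)
    inc2 = not desc2 and not hidx.is_ancestor_or_self(h2, h)
    if (inc1 and desc2) or (inc2 and desc1):
        return HOST_SWITCH
    if hidx.incomparable(h1, h2) and hidx.lca(h1, h2) == h:
        return COSPECIATION
    if desc1 and desc2:
        return DUPLICATION
    return None


def loss_contribution(hidx: TreeIndex, h: int, h1: int, h2: int) -> int:
    """Number of losses accompanying the event at ``(h, h1, h2)``.

    Host-switch: arcs down to the non-switching (descendant) child host.
    Cospeciation: arcs down to both child hosts minus the two divergence arcs.
    Duplication: arcs down to both child hosts.
    """
    e = classify_event(hidx, h, h1, h2)
    if e is None:
        raise ValueError("no valid event for this host triple")
    if e == HOST_SWITCH:
        if hidx.incomparable(h, h2):
            return hidx.distance(h, h1)
        return hidx.distance(h, h2)
    if e == COSPECIATION:
        return hidx.distance(h, h1) + hidx.distance(h, h2) - 2
    return hidx.distance(h, h1) + hidx.distance(h, h2)


@dataclass
class ValidationReport:
    valid: bool
    violations: list  # list[tuple[node name, message]]


def validate_reconciliation(phi: Reconciliation, inst: ProblemInstance) -> ValidationReport:
    """Check every leaf and internal clause of the reconciliation definition.

    Invalidity is a result (with per-node diagnostics), not an error.
    """
    P = inst.parasite
    d = phi.as_dict()
    violations = []
    for p in P.postorder():
        if p not in d:
            violations.append((P.name[p], "no assignment"))
            continue
        h, e = d[p]
        if P.is_leaf(p):
            if h != inst.sigma[p]:
                violations.append(
                    (P.name[p], f"leaf must map to sigma image {inst.host.name[inst.sigma[p]]!r}")
                )
            if e != TERMINAL:
                violations.append((P.name[p], f"leaf event must be {TERMINAL}, got {e}"))
        else:
            p1, p2 = P.children[p]
            if p1 not in d or p2 not in d:
                continue  # reported at the child
            want = classify_event(inst.hidx, h, d[p1][0], d[p2][0])
            if want is None:
                violations.append((P.name[p], "child hosts admit no valid event"))
            elif e != want:
                violations.append((P.name[p], f"event should be {want}, got {e}"))
    return ValidationReport(valid=not violations, violations=violations)


def event_vector(phi: Reconciliation, inst: ProblemInstance) -> tuple:
    """(#C, #D, #S, #L) of a valid reconciliation."""
    report = validate_reconciliation(phi, inst)
    if not report.valid:
        raise ValueError(f"invalid reconciliation: {report.violations}")
    nc = nd = ns = nl = 0
    d = phi.as_dict()
    for p in inst.internal_parasites:
        h, e = d[p]
        p1, p2 = inst.parasite.children[p]
        nl += loss_contribution(inst.hidx, h, d[p1][0], d[p2][0])
        if e == COSPECIATION:
            nc += 1
        elif e == DUPLICATION:
            nd += 1
        else:
            ns += 1
    return (nc, nd, ns, nl)


def reconciliation_cost(vec: Sequence, costs: Sequence) -> Fraction:
    """Dot product of an event vector with a cost vector (exact)."""
    return sum((Fraction(c) * v for c, v in zip(costs, vec)), Fraction(0))


def enumerate_all_valid(inst: ProblemInstance) -> Iterator[Reconciliation]:
    """ORACLE: every valid reconciliation, by exhaustive product over host nodes.

    Intended for small instances only; uses none of the graph machinery.
    """
    P, H = inst.parasite, inst.host
    internals = inst.internal_parasites
    hosts = list(H.postorder())
    base = {p: inst.sigma[p] for p in P.leaves}
    for combo in itertools.product(hosts, repeat=len(internals)):
        phi_h = dict(base)
        phi_h.update(zip(internals, combo))
        events = {}
        ok = True
        for p in internals:
            p1, p2 = P.children[p]
            e = classify_event(inst.hidx, phi_h[p], phi_h[p1], phi_h[p2])
            if e is None:
                ok = False
                break
            events[p] = e
        if not ok:
            continue
        d = {p: (phi_h[p], events.get(p, TERMINAL)) for p in P.postorder()}
        yield Reconciliation.from_dict(d)


def brute_force_optimal(inst: ProblemInstance):
    """ORACLE: ``(optimal cost, [optimal reconciliations])`` by exhaustive filtering."""
    best = None
    best_list: list = []
    for phi in enumerate_all_valid(inst):
        cost = reconciliation_cost(event_vector(phi, inst), inst.costs)
        if best is None or cost < best:
            best = cost
            best_list = [phi]
        elif cost == best:
            best_list.append(phi)
    if best is None:
        raise InfeasibleError("instance admits no valid reconciliation")
    return best, best_list
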