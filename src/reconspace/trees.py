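"""Rooted full binary phylogenies and the topology queries the reconciliation model needs.

Trees are *ordered*: the left-to-right child order of the Newick text is
significant (the AND/OR machinery downstream treats the two children of a
node as an ordered couple).  Node identifiers are dense integers equal to the
postorder index, so every child id is smaller than its parent's and the root
is ``len(tree) - 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import dendropy

__all__ = [
    "PhyloTree",
    "TreeIndex",
    "Relation",
    "TreeError",
    "MappingError",
    "parse_newick",
    "parse_leaf_mapping",
    "index_tree",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or trees violating the full-binary model."""


class MappingError(ValueError):
    """Raised for malformed or non-total leaf association maps."""


class Relation(Enum):
    EQUAL = "equal"
    ANCESTOR = "ancestor"  # first argument is a *proper* ancestor of the second
    DESCENDANT = "descendant"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class PhyloTree:
    """A rooted, ordered, full binary tree with postorder-indexed nodes.

    ``children[v]`` is the ordered couple ``(first, second)`` for internal
    nodes and ``None`` for leaves; ``parent[root] is None``.  ``name[v]`` is
    the leaf label for leaves and the (possibly auto-generated) name for
    internal nodes.
    """

    children: tuple  # tuple[Optional[tuple[int, int]], ...]
    parent: tuple  # tuple[Optional[int], ...]
    name: tuple  # tuple[str, ...]
    tag: str = "t"
    leaf_by_label: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return len(self.children) - 1

    def is_leaf(self, v: int) -> bool:
        return self.children[v] is None

    @property
    def leaves(self) -> list:
        return [v for v in range(len(self)) if self.is_leaf(v)]

    @property
    def n_leaves(self) -> int:
        return (len(self) + 1) // 2

    def postorder(self) -> Iterator[int]:
        return iter(range(len(self)))

    def internal_postorder(self) -> Iterator[int]:
        return (v for v in range(len(self)) if not self.is_leaf(v))

    def node_id(self, name: str) -> int:
        try:
            return self.name.index(name)
        except ValueError:
            raise TreeError(f"unknown node name {name!r} in tree {self.tag!r}") from None

    def to_newick(self) -> str:
        """Serialize topology, child order and all node names (no branch lengths)."""

        def rec(v: int) -> str:
            if self.is_leaf(v):
                return self.name[v]
            a, b = self.children[v]
            return f"({rec(a)},{rec(b)}){self.name[v]}"

        return rec(self.root) + ";"


def parse_newick(text: str, tag: str = "t") -> PhyloTree:
    """Parse a single rooted Newick tree into a :class:`PhyloTree`.

    Branch lengths and comments are accepted and discarded (the model is
    purely topological); quoted labels are supported.  Unnamed internal nodes
    are auto-named ``"<tag>#<postorder-index>"`` so that diagnostics and
    outputs are stable.

    Raises :class:`TreeError` on syntax errors, duplicate or missing leaf
    labels, and any node whose child count is neither 0 nor 2.
    """
    text = text.strip()
    if not text:
        raise TreeError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    # Postorder traversal fixing dense ids; verify full-binary along the way.
    nodes = list(dtree.preorder_node_iter())
    order = []

    def post(nd) -> None:
        for ch in nd.child_nodes():
            post(ch)
        order.append(nd)

    post(dtree.seed_node)
    if len(order) != len(nodes):
        raise TreeError("malformed tree traversal")

    idx = {id(nd): i for i, nd in enumerate(order)}
    children: list = []
    parent: list = [None] * len(order)
    names: list = []
    seen_leaves: dict = {}
    for i, nd in enumerate(order):
        kids = nd.child_nodes()
        if len(kids) == 0:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                raise TreeError(f"leaf #{i} has no label")
            if label in seen_leaves:
                raise TreeError(f"duplicate leaf label {label!r}")
            seen_leaves[label] = i
            children.append(None)
            names.append(label)
        elif len(kids) == 2:
            a, b = idx[id(kids[0])], idx[id(kids[1])]
            children.append((a, b))
            parent[a] = i
            parent[b] = i
            label = nd.label or (nd.taxon.label if nd.taxon is not None else None)
            names.append(label if label else f"{tag}#{i}")
        else:
            where = nd.label or ",".join(
                (k.taxon.label if k.taxon else k.label or "?") for k in kids
            )
            raise TreeError(
                f"node ({where}) has {len(kids)} children; the model requires full binary trees"
            )
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise TreeError(f"duplicate node names: {dupes}")
    return PhyloTree(
        children=tuple(children),
        parent=tuple(parent),
        name=tuple(names),
        tag=tag,
        leaf_by_label=dict(seen_leaves),
    )


def parse_leaf_mapping(text: str, parasite: PhyloTree, host: PhyloTree) -> dict:
    """Parse the two-column parasite→host leaf association TSV into ``{pid: hid}``.

    Lines starting with ``#`` are comments; surrounding whitespace is trimmed;
    labels are matched exactly (case-sensitive).  The map must be total over
    the parasite leaves; all problems are reported exhaustively.
    """
    sigma: dict = {}
    errors: list = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2 or not all(parts):
            parts = line.split()
        if len(parts) != 2:
            errors.append(f"line {lineno}: expected two tab-separated labels, got {line!r}")
            continue
        plab, hlab = parts
        pid = parasite.leaf_by_label.get(plab)
        hid = host.leaf_by_label.get(hlab)
        if pid is None:
            errors.append(f"line {lineno}: unknown parasite leaf {plab!r}")
            continue
        if hid is None:
            errors.append(f"line {lineno}: unknown host leaf {hlab!r}")
            continue
        if pid in sigma and sigma[pid] != hid:
            errors.append(
                f"line {lineno}: parasite leaf {plab!r} mapped to both "
                f"{host.name[sigma[pid]]!r} and {hlab!r}"
            )
            continue
        sigma[pid] = hid
    missing = [parasite.name[v] for v in parasite.leaves if v not in sigma]
    if missing:
        errors.append("missing: " + ", ".join(sorted(missing)))
    if errors:
        raise MappingError("; ".join(errors))
    return sigma


class TreeIndex:
    """Depth, O(1) ancestry and LCA queries over a :class:`PhyloTree`.

    Ancestry is answered from preorder in/out intervals.  "Descendant" and
    "ancestor" include the node itself unless stated otherwise; the
    :class:`Relation` returned by :meth:`relation` uses the proper
    (irreflexive) reading and reports equality separately.
    """

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        n = len(tree)
        self.depth = [0] * n
        self.tin = [0] * n
        self.tout = [0] * n
        clock = 0
        stack = [(tree.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                self.tout[v] = clock
                continue
            self.tin[v] = clock
            clock += 1
            stack.append((v, True))
            if not tree.is_leaf(v):
                a, b = tree.children[v]
                self.depth[a] = self.depth[v] + 1
                self.depth[b] = self.depth[v] + 1
                stack.append((b, False))
                stack.append((a, False))

    def _check(self, v: int) -> None:
        if not 0 <= v < len(self.tree):
            raise TreeError(f"unknown node id {v}")

    def is_ancestor_or_self(self, u: int, v: int) -> bool:
        """True iff u is an ancestor of v, including u == v."""
        self._check(u)
        self._check(v)
        return self.tin[u] <= self.tin[v] and self.tin[v] < self.tout[u]

    def relation(self, u: int, v: int) -> Relation:
        if u == v:
            self._check(u)
            return Relation.EQUAL
        if self.is_ancestor_or_self(u, v):
            return Relation.ANCESTOR
        if self.is_ancestor_or_self(v, u):
            return Relation.DESCENDANT
        return Relation.INCOMPARABLE

    def incomparable(self, u: int, v: int) -> bool:
        return self.relation(u, v) is Relation.INCOMPARABLE

    def lca(self, u: int, v: int) -> int:
        self._check(u)
        self._check(v)
        while not self.is_ancestor_or_self(u, v):
            u = self.tree.parent[u]
        return u

    def distance(self, u: int, v: int) -> int:
        """Number of arcs between two *comparable* nodes (|depth(u) - depth(v)|).

        Raises :class:`TreeError` on an incomparable pair: the loss model only
        ever measures distances along a directed path.
        """
        rel = self.relation(u, v)
        if rel is Relation.INCOMPARABLE:
            raise TreeError(
                f"distance undefined for incomparable nodes "
                f"{self.tree.name[u]!r}, {self.tree.name[v]!r}"
            )
        return abs(self.depth[u] - self.depth[v])

    def diameter(self) -> int:
        """Maximum number of arcs on an (undirected) path between two nodes."""
        leaves = self.tree.leaves
        best = 0
        for i, u in enumerate(leaves):
            for v in leaves[i:]:
                d = self.depth[u] + self.depth[v] - 2 * self.depth[self.lca(u, v)]
                if d > best:
                    best = d
        return best


def index_tree(tree: PhyloTree) -> TreeIndex:
    return TreeIndex(tree)
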