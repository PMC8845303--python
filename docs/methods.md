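# Methods

## Model

Hosts and parasites are rooted, *ordered*, full binary trees; the
left-to-right child order of the Newick input is preserved and meaningful
(the two children of every node form an ordered couple throughout the
machinery). Branch lengths and comments are accepted and discarded — the
model is purely topological and undated; time-feasibility of host-switches
is out of scope.

A reconciliation maps every parasite node to a host node. Leaves are pinned
to the observed associations σ with the terminal event T. For an internal
parasite node p with children (p₁, p₂) mapped to (h, h₁, h₂):

- **host-switch (S)** if exactly one of h₁, h₂ is incomparable to h and the
  other is a descendant of h;
- **cospeciation (C)** if LCA(h₁, h₂) = h and h₁, h₂ are incomparable;
- **duplication (D)** if both h₁, h₂ are descendants of h and neither of the
  previous cases applies;
- any other configuration is invalid.

"Descendant" and "ancestor" include the node itself everywhere; this single
convention resolves all boundary cases (e.g. (h, h, h') with h' below h is a
duplication, and the descendant side of a switch may stay exactly at h).
The S and C cases cannot overlap (a child incomparable to h forces
LCA(h₁,h₂) ≠ h), so testing S, then C, then D as catch-all realizes the
"exactly one applies" contract. Both children incomparable to h is rejected.

Losses are a per-node count, not a node event: a switch charges the arcs
from h down to the *descendant-side* child host, a cospeciation charges
d(h,h₁) + d(h,h₂) − 2 (the two divergence arcs are free), a duplication
charges d(h,h₁) + d(h,h₂). Host-tree distances are only ever taken along
directed paths, so `distance()` on incomparable nodes is an error by design,
not ∞.

Cost = (#C, #D, #S, #L) · (c(C), c(D), c(S), c(L)). Costs are parsed as
decimal strings into exact rationals and all comparisons are exact; with
float arithmetic, ties — which decide the *membership of the optimal set*
and therefore every count in the package — would be resolved by rounding
noise. Negative costs are allowed (the literature uses (−1,1,1,1)).

## The reconciliation graph

The DP value f(p, h, e) is the minimum cost of reconciling the parasite
subtree at p with p mapped to h under event e (0 for a leaf's own
(p, σ(p), T) cell, ∞ otherwise). The classical construction materializes an
AND node for every compatible pair of child cells — O(n³m) of them — and
then prunes non-optimal arcs, non-optimal root cells and unreachable AND
nodes. This package computes the same pruned graph without ever touching the
non-optimal part:

1. **Values first.** For a fixed cell, the objective separates into
   independent minimizations over the two child hosts. With
   Aᵢ(x) = Fᵢ(x) + c(L)·depth(x), where Fᵢ(x) = minₑ f(pᵢ, x, e), subtree
   minima of Aᵢ absorb the per-arc loss charges, and a top-down "outside"
   pass gives the minimum of Fᵢ over the hosts incomparable to each h (the
   landing sites of a switcher, which incur no loss). Cospeciation reads two
   subtree minima (one per child subtree of h, both orientations);
   duplication decomposes the both-descendants-minus-cospeciation pair set
   into four product regions ({h}×sub(h), sub(h)×{h}, sub(h₁)², sub(h₂)²);
   host-switch combines a descendant-side subtree minimum with an outside
   minimum. This yields all f(p, ·, ·) in O(n) per parasite node. Infeasible
   cells are a large integer sentinel; rational costs are rescaled by the
   LCM of their denominators so all DP arithmetic is integral and exact.

2. **Materialize only what survives.** Starting from the root cells whose
   value equals the optimum, each needed cell enumerates its value-achieving
   child-host pairs by a vectorized scan of the n×n pair matrix under the
   event's mask, and the achieving events on each side (those attaining
   Fᵢ — for a separable objective a pair achieves the cell value iff both
   sides attain their own minima). Only these AND nodes and the cells they
   reference are created.

A node survives the classical pruning plus a dead-node sweep iff it is
value-achieving and reachable from a surviving start cell, so the lazy
construction produces exactly that graph, and every materialized node lies
on at least one solution subtree — the precondition the class-enumeration
algorithms need. (The paper-style sweep-or-no-sweep distinction is moot
here: dead nodes are never created.) Correctness is not argued only on
paper: the structural audit and the brute-force oracle comparison run over
the whole test grid.

Counting is one bottom-up pass (goal = 1, AND = product, OR = sum, total =
sum over start nodes) in unbounded integers; enumeration is the standard
nested-generator traversal with O(m) delay; G/O start-set restriction is a
reachability view sharing node objects.

## Equivalence classes

- **V (event vector).** EV(s) — the set of event vectors achievable below
  OR⁺ node s, with exact multiplicities — is computed bottom-up: goal nodes
  hold {(0,0,0,0)}; an OR node takes, per grandchild couple, the Cartesian
  sum of its children's tables shifted by the couple's loss contribution and
  its own event's unit vector. Cartesian sums are naive hash-map
  convolutions; the number of distinct vectors per node is polynomially
  bounded (#C+#D+#S is fixed at the internal-node count and losses are
  bounded by size × diameter). Counting is fused into the same pass — the
  per-vector multiplicities are exactly the "replace any by all"
  aggregation — and representatives/within-class members come from the
  standard backtrack over Eq.-style decompositions (first decomposition in
  canonical order for the deterministic representative; all decompositions
  for within-class enumeration, which is duplicate-free because distinct
  decompositions differ in a triple or a child vector).

- **E and CD.** An OR⁺ node's *color* is (p, e) for E, and (p, h, e) with
  the host masked to "?" on switches for CD; a class is a total map from
  parasite nodes to color payloads. Classes are enumerated by a top-down
  recursion over sets O of same-colored OR⁺ nodes: partition the grandchild
  couples of O by color couple; for each couple of colors, recurse on the
  first-side node set, then — *given* the surviving first-side roots Õ₁ —
  recurse on the second-side nodes compatible with Õ₁, and emit the merged
  class together with the set of nodes in O that root a solution realizing
  it. The root-set bookkeeping is what prevents invalid cross-combinations
  and duplicate emissions; both guarantees (each class exactly once; emitted
  root sets equal the true per-class root sets) are asserted against the
  oracle. One generic code path serves both relations, parameterized only by
  the coloring. Lazy generators keep the delay polynomial (O(m·n²) couple
  operations per yield); a per-yield operation counter makes the bound
  testable without wall clocks. The published pseudocode figure for this
  recursion is not legible in the source text; the control flow implemented
  here is the one the correctness proof describes, and the proof's
  input/output contract is what the tests pin down.

- **Per-class study.** Pruning the graph to the OR⁺ nodes whose color
  corroborates a class (then re-closing bottom-up and restricting to
  reachable nodes) yields a graph whose solutions are exactly the class
  members; counting, representative extraction and enumeration are then the
  generic graph operations. An unrealized class prunes to the empty graph.

- **Event supports.** Computed in a single pass from below-counts (solutions
  under a node) and above-counts (extensions of a node to a start node):
  decomposability guarantees each solution contains exactly one OR⁺ node
  per parasite node, so through-counts partition the solution space. The
  class-pruning route recomputes the same numbers independently in the test
  suite. Nodes with exactly one supported event are reported as
  *consistent*.

## Fixtures and what the tests show

`toy12` (3-leaf host, 3-leaf parasite) is small enough that all 5² internal
assignments can be checked by hand: 12 valid reconciliations, 6 V-classes
with counts {4,2,2,2,1,1}, 5 E-classes with sizes {6,2,2,1,1}, 5 CD-classes,
and a unique optimum with vector (2,0,0,0) under (0,1,1,1) and (−1,1,1,1).
All frozen test constants were recomputed with the brute-force oracle before
being frozen.

`random_instance` grows tree shapes by uniform random leaf splitting and
samples σ uniformly and independently per parasite leaf, reproducibly per
seed. This emulates the *combinatorial* diversity of real instances —
arbitrary shapes, non-injective/non-surjective associations — but not their
biological structure: real host/parasite pairs have correlated topologies,
widespread cospeciation signal, and (in the gene/species setting) highly
non-uniform association multiplicities. Passing the oracle-equivalence grid
therefore certifies algorithmic correctness on arbitrary topologies, not any
biological claim about real datasets.

Problem sizes used by the shipped test suite and acceptance script, chosen
to keep the oracle side exhaustive and the whole run desk-scale: the oracle
grid uses 2–5 leaves per tree (50 seeds × six cost vectors; the oracle
enumerates up to 9⁴ assignments per instance), the delay check uses one
40-leaf instance (first 500 E-classes under (0,1,1,0), operation count per
yield bounded by 8·m·n²), and the big-count smoke test uses one 100-leaf
instance under (0,1,1,0), where counts reach ~10³⁰–10⁴⁰ and are verified by
two independent routes. The all-zero cost vector is exercised only at small
sizes: with every cell optimal the pruned graph itself grows impractically
large at 100 leaves, which is a property of the solution space, not of the
implementation.

## Numerical and design choices

- Exact rationals for costs/values; exact big integers for counts
  (serialized as decimal strings in CLI output).
- Deterministic canonical orders everywhere: nodes by (parasite postorder,
  host postorder, event C<D<S<T); AND children by (h₁, e₁, h₂, e₂); class
  and vector streams sorted by these keys. Identical inputs give
  byte-identical outputs.
- Internal nodes without names are auto-named `tag#postorder` so every
  output can reference nodes stably.
- Infeasibility is reported explicitly (CLI exit code 3), although a
  well-formed instance always admits at least one reconciliation (map every
  internal parasite to the host root).
- The brute-force oracle is deliberately implemented with none of the graph
  machinery and is quadratic-to-exponential; it guards every algorithm but
  is not part of the production path.

## Known limitations

- Undated trees only: no time-consistency filtering of host-switches, no
  dated/ranked variants, no multifurcations, no multiple associations per
  leaf.
- Counting E-/CD-classes is only available via enumeration (no faster
  counting method is known to us).
- The EV tables can grow large under cost vectors with c(L) = 0 on big
  instances; V-class operations are then memory-bound.
- No visualization; outputs are TSV/JSON-lines for downstream tooling.
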