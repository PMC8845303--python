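# reconspace

Event-based parsimony reconciliation of a parasite phylogeny with its host
phylogeny — and exact, structured access to the *entire* space of optimal
reconciliations.

## The problem

Given rooted full binary trees *H* (hosts) and *P* (parasites) and a map
σ : L(P) → L(H) of observed associations between extant species, a
reconciliation φ : V(P) → V(H) assigns every parasite node a host. Each
internal parasite node *p* with children *p₁, p₂* induces exactly one event:

- **C** (cospeciation): φ(p) is the LCA of φ(p₁) and φ(p₂), which are
  incomparable — parasite and host diverged together;
- **S** (host-switch): one child's host is incomparable to φ(p) (the
  switcher), the other's is a descendant of φ(p);
- **D** (duplication): both children's hosts descend from φ(p) and neither
  of the above applies — the parasite diverged on its host lineage;
- leaves carry the terminal event **T** and must satisfy φ(p) = σ(p).

Each internal node also contributes **losses** (L), counted as host-tree
arcs the parasite silently tracked: d(φ(p),φ(p₁)) + d(φ(p),φ(p₂)) − 2 for a
cospeciation, d + d for a duplication, and the arcs on the non-switching
side only for a host-switch. With a cost vector c⃗ = (c(C), c(D), c(S), c(L))
the cost of φ is c⃗ · e⃗(φ), where e⃗(φ) = (#C, #D, #S, #L) is the *event
vector*; the problem is to find — and here, to count, enumerate and
summarize — all minimum-cost reconciliations.

The number of co-optimal reconciliations routinely explodes (real datasets
reach 10⁴⁰ and beyond), so the package represents them implicitly as the
solution subtrees of a pruned acyclic decomposable AND/OR graph (the
*reconciliation graph*) built from the dynamic program over cells (p, h, e).
On top of that graph it provides, without ever enumerating the solutions
themselves:

- exact solution counts (unbounded integers) and linear-delay enumeration;
- **V-equivalence** classes (solutions grouped by event vector), with
  per-class counts, representatives and solution-space proportions;
- **E-equivalence** classes (grouped by the per-node event map) and
  **CD-equivalence** classes (per-node events plus the hosts of non-switch
  nodes), enumerated with polynomial delay directly from the graph;
- per-class counting / representative extraction / within-class enumeration
  by pruning the graph to one class;
- per-node **event supports** (the share of optimal reconciliations
  assigning a given event to a given parasite node) and the list of nodes
  with a consistent event across the whole solution space.

All arithmetic is exact: costs are rationals, counts are big integers. A
brute-force oracle (exhaustive assignment on small instances) ships with the
package and backs the test suite.

Audience: researchers in cophylogenetics / host–parasite coevolution (and
the formally identical gene-tree/species-tree setting) who need more than a
single arbitrary optimal reconciliation.

## Worked example

The bundled toy instance has host tree `(ha,(hb,hc)hx)hr;`, parasite tree
`((pa,pb)p1,pc)p0;` and associations pa→hb, pb→hc, pc→ha:

```sh
reconspace fixture toy12 --out-dir fx
reconspace count --host fx/host.nwk --parasite fx/parasite.nwk \
    --mapping fx/mapping.tsv --cost "0,0,0,0"
# 12
reconspace frequencies --host fx/host.nwk --parasite fx/parasite.nwk \
    --mapping fx/mapping.tsv --cost "0,0,0,0"
```

```
C	D	S	L	count	proportion
0	0	2	0	4	33.3333
0	0	2	1	2	16.6667
1	0	1	0	2	16.6667
1	0	1	1	2	16.6667
0	2	0	5	1	8.3333
2	0	0	0	1	8.3333
```

Under the all-zero cost vector every valid reconciliation is optimal: there
are 12 of them, falling into 6 event-vector classes — e.g. a third of the
solution space uses two host-switches and no losses, while the unique
all-cospeciation history (2, 0, 0, 0) accounts for 8.3% of it. Under the
standard cost vector (0, 1, 1, 1) that all-cospeciation history is the
unique optimum:

```sh
reconspace support --host fx/host.nwk --parasite fx/parasite.nwk \
    --mapping fx/mapping.tsv --cost "0,1,1,1"
```

```
parasite_node	event	count	proportion
pa	T	1	100.0000
pb	T	1	100.0000
p1	C	1	100.0000
pc	T	1	100.0000
p0	C	1	100.0000
# consistent internal nodes: p1,p0
```

Other subcommands: `cost`, `solutions` (stream, `--limit`), `classes
--relation {vector,event,cd} [--with-sizes]` (JSON lines; `--with-sizes`
also reports the reduction = classes / solutions), `class-info` (count,
representative or members of one class), `fixture random` (seeded random
instances). The same operations are available as library functions
(`reconspace.build_graph`, `count_solutions`, `enumerate_classes`,
`event_support`, …).

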