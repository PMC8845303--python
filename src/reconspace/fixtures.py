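"""Hand-analyzed toy instance and a seeded random-instance generator.

``toy12`` is a three-leaf-parasite / three-leaf-host instance small enough to
be analyzed by hand (and by the brute-force oracle): under the all-zero cost
vector every one of its 12 valid reconciliations is optimal, splitting into
6 event-vector classes, 5 per-node-event classes and 5 event+host classes.

``random_instance`` grows uniform random full binary tree shapes by
repeated leaf splitting and samples the leaf associations uniformly and
independently; identical ``(n_host, n_parasite, seed)`` triples reproduce
identical instances bit-for-bit.
"""

from __future__ import annotations

import random
from typing import Sequence

from .model import ProblemInstance, parse_cost_vector
from .trees import parse_newick, parse_leaf_mapping

__all__ = ["toy12", "random_instance", "TOY12_HOST", "TOY12_PARASITE", "TOY12_MAPPING"]

TOY12_HOST = "(ha,(hb,hc)hx)hr;"
TOY12_PARASITE = "((pa,pb)p1,pc)p0;"
TOY12_MAPPING = "pa\thb\npb\thc\npc\tha\n"

#: the five cost vectors commonly used in the reconciliation literature
#: (favor cospeciations; minimize incongruence; penalize switches twice/thrice;
#: free cospeciations and losses), plus the degenerate all-zero vector under
#: which every valid reconciliation is optimal.
LITERATURE_COSTS = (
    "-1,1,1,1",
    "0,1,1,1",
    "0,1,2,1",
    "0,2,3,1",
    "0,1,1,0",
)
TEST_COSTS = LITERATURE_COSTS + ("0,0,0,0",)


def toy12(costs: Sequence = (0, 0, 0, 0)) -> ProblemInstance:
    """The hand-analyzed toy instance (12 valid reconciliations)."""
    host = parse_newick(TOY12_HOST, tag="h")
    parasite = parse_newick(TOY12_PARASITE, tag="p")
    sigma = parse_leaf_mapping(TOY12_MAPPING, parasite, host)
    return ProblemInstance(host, parasite, sigma, tuple(costs))


def _random_topology(n_leaves: int, rng: random.Random, prefix: str) -> str:
    """Uniform leaf-splitting shape as a Newick string with labeled leaves."""
    tree: list = [None]  # a leaf slot; internal = [left, right]
    leaves = [tree]
    for _ in range(n_leaves - 1):
        node = leaves[rng.randrange(len(leaves))]
        left, right = [None], [None]
        node[:] = [left, right]
        leaves.remove(node)
        leaves.extend((left, right))

    counter = [0]

    def emit(node: list) -> str:
        if len(node) == 1:
            lab = f"{prefix}{counter[0]}"
            counter[0] += 1
            return lab
        return f"({emit(node[0])},{emit(node[1])})"

    return emit(tree) + ";"


def random_instance(
    n_host_leaves: int,
    n_parasite_leaves: int,
    seed: int,
    costs: Sequence = (0, 1, 1, 1),
) -> ProblemInstance:
    """Seeded random instance: random shapes, uniform independent associations."""
    if n_host_leaves < 1 or n_parasite_leaves < 1:
        raise ValueError("trees need at least one leaf each")
    rng = random.Random(seed)
    host = parse_newick(_random_topology(n_host_leaves, rng, "h"), tag="h")
    parasite = parse_newick(_random_topology(n_parasite_leaves, rng, "p"), tag="p")
    host_leaves = host.leaves
    sigma = {p: host_leaves[rng.randrange(len(host_leaves))] for p in parasite.leaves}
    if isinstance(costs, str):
        costs = parse_cost_vector(costs)
    return ProblemInstance(host, parasite, sigma, tuple(costs))
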