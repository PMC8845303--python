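import pytest
from collections import Counter, defaultdict

from reconspace import (
    brute_force_optimal,
    build_graph,
    event_vector,
    toy12,
)
from reconspace.equivalence import ClassAssignment
from reconspace.model import reconciliation_cost


@pytest.fixture(scope="session")
def toy():
    """The hand-analyzed toy instance under the all-zero cost vector."""
    return toy12()


@pytest.fixture(scope="session")
def toy_graph(toy):
    return build_graph(toy)


@pytest.fixture(scope="session")
def toy_optima(toy):
    cost, opts = brute_force_optimal(toy)
    return cost, opts


def oracle_vector_tally(inst, optima):
    return dict(Counter(event_vector(phi, inst) for phi in optima))


def oracle_class_groups(relation, optima):
    groups = defaultdict(list)
    for phi in optima:
        groups[ClassAssignment.from_reconciliation(relation, phi)].append(phi)
    return groups


def oracle_support(optima):
    counts = defaultdict(Counter)
    for phi in optima:
        for p, h, e in phi.triples():
            counts[p][e] += 1
    return {p: dict(c) for p, c in counts.items()}
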