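from fractions import Fraction

import pytest

from reconspace import (
    brute_force_optimal,
    build_graph,
    class_info,
    count_solutions,
    enumerate_classes,
    event_support,
    event_vector,
    node_color,
    parse_cost_vector,
    prune_to_class,
    toy12,
    validate_reconciliation,
)
from reconspace.equivalence import ClassAssignment
from reconspace.fixtures import LITERATURE_COSTS, TEST_COSTS, random_instance
from conftest import oracle_class_groups, oracle_support


def _e_class(toy, **events):
    P = toy.parasite
    items = {p: "T" for p in P.leaves}
    for name, e in events.items():
        items[P.node_id(name)] = e
    return ClassAssignment("E", tuple(sorted(items.items())))


class TestColors:
    def test_projections(self):
        assert node_color((4, 3, "C"), "E") == (4, "C")
        assert node_color((4, 3, "C"), "CD") == (4, 3, "C")
        assert node_color((4, 3, "S"), "CD") == (4, None, "S")

    def test_unknown_relation(self):
        with pytest.raises(ValueError):
            node_color((0, 0, "T"), "X")


class TestToyClasses:
    def test_five_e_classes_with_expected_sizes(self, toy, toy_graph):
        got = list(enumerate_classes(toy_graph, "E"))
        assert len(got) == 5
        sizes = sorted(class_info(toy_graph, ca, "count") for ca, _ in got)
        assert sizes == [1, 1, 2, 2, 6]
        events = {
            tuple(ca.payload(p) for p in (toy.parasite.node_id("p1"),
                                          toy.parasite.node_id("p0")))
            for ca, _ in got
        }
        assert events == {("C", "C"), ("C", "S"), ("S", "C"), ("S", "S"), ("D", "D")}

    def test_five_cd_classes_refining_e(self, toy_graph):
        cd = list(enumerate_classes(toy_graph, "CD"))
        assert len(cd) == 5
        assert sorted(class_info(toy_graph, ca, "count") for ca, _ in cd) == [1, 1, 2, 2, 6]

    def test_single_leaf_instance_single_class(self):
        g = build_graph(random_instance(1, 1, seed=0))
        for rel in ("E", "CD"):
            classes = list(enumerate_classes(g, rel))
            assert len(classes) == 1

    def test_consistent_nodes_under_unit_costs(self):
        g = build_graph(toy12(parse_cost_vector("0,1,1,1")))
        sup = event_support(g)
        internal = [p for p in sup.counts if not g.inst.parasite.is_leaf(p)]
        assert all(p in sup.consistent_nodes for p in internal)
        assert all(sup.consistent_nodes[p] == "C" for p in internal)


class TestPruneToClass:
    def test_class_counts(self, toy, toy_graph):
        assert count_solutions(prune_to_class(toy_graph, _e_class(toy, p1="S", p0="S"))) == 6
        assert count_solutions(prune_to_class(toy_graph, _e_class(toy, p1="C", p0="C"))) == 1
        assert count_solutions(prune_to_class(toy_graph, _e_class(toy, p1="S", p0="C"))) == 2

    def test_unrealized_class_gives_empty_graph(self, toy, toy_graph):
        sub = prune_to_class(toy_graph, _e_class(toy, p1="D", p0="C"))
        assert count_solutions(sub) == 0
        assert not sub.nodes
        with pytest.raises(ValueError, match="empty class"):
            class_info(toy_graph, _e_class(toy, p1="D", p0="C"), "representative")

    def test_malformed_assignments_rejected(self, toy, toy_graph):
        with pytest.raises(ValueError, match="total"):
            class_info(toy_graph, ClassAssignment("E", ((0, "T"),)), "count")
        bad_leaf = {p: "C" for p in toy.parasite.postorder()}
        with pytest.raises(ValueError, match="terminal"):
            class_info(toy_graph, ClassAssignment("E", tuple(sorted(bad_leaf.items()))), "count")

    def test_representative_contract(self, toy, toy_graph):
        cls = _e_class(toy, p1="S", p0="C")
        rep = class_info(toy_graph, cls, "representative")
        assert validate_reconciliation(rep, toy).valid
        assert ClassAssignment.from_reconciliation("E", rep) == cls

    def test_pruned_graph_is_sound(self, toy, toy_graph):
        sub = prune_to_class(toy_graph, _e_class(toy, p1="S", p0="S"))
        sub.audit()
        members = list(class_info(toy_graph, _e_class(toy, p1="S", p0="S"), "enumerate"))
        assert len(members) == len(set(members)) == 6


class TestToySupport:
    def test_support_tally(self, toy, toy_graph):
        sup = event_support(toy_graph)
        p1, p0 = toy.parasite.node_id("p1"), toy.parasite.node_id("p0")
        assert sup.total == 12
        assert sup.counts[p1] == {"C": 3, "S": 8, "D": 1}
        assert sup.counts[p0] == {"C": 3, "S": 8, "D": 1}
        props = sup.proportions()
        assert props[p1]["S"] == Fraction(2, 3)

    def test_per_node_sums_partition_the_total(self, toy_graph):
        sup = event_support(toy_graph)
        for by_e in sup.counts.values():
            assert sum(by_e.values()) == sup.total


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("cv", TEST_COSTS)
    @pytest.mark.parametrize("relation", ["E", "CD"])
    def test_lemma_guarantees(self, seed, cv, relation):
        """Every class exactly once; root sets equal the class-member roots."""
        inst = random_instance(4, 4, seed, costs=parse_cost_vector(cv))
        _, opts = brute_force_optimal(inst)
        groups = oracle_class_groups(relation, opts)
        g = build_graph(inst)
        got = list(enumerate_classes(g, relation))
        assert len(got) == len(groups)
        assert {ca for ca, _ in got} == set(groups)
        root = inst.parasite.root
        for ca, roots in got:
            assert class_info(g, ca, "count") == len(groups[ca])
            assert {r.label for r in roots} == {
                (root, m.host_of(root), m.event_of(root)) for m in groups[ca]
            }

    @pytest.mark.parametrize("seed", range(6))
    def test_cd_refines_e(self, seed):
        inst = random_instance(4, 4, seed, costs=(0, 0, 0, 0))
        g = build_graph(inst)
        e_classes = {ca for ca, _ in enumerate_classes(g, "E")}
        cd_classes = [ca for ca, _ in enumerate_classes(g, "CD")]
        assert len(cd_classes) >= len(e_classes)
        for ca in cd_classes:
            projected = ClassAssignment(
                "E", tuple((p, e) for p, (e, _h) in ca.items))
            assert projected in e_classes

    @pytest.mark.parametrize("cv", [c for c in LITERATURE_COSTS if c.endswith("1")])
    @pytest.mark.parametrize("seed", range(4))
    def test_positive_loss_cost_fixes_the_vector_per_e_class(self, cv, seed):
        # with c(L) > 0 all members of an E class share one event vector
        inst = random_instance(4, 4, seed, costs=parse_cost_vector(cv))
        _, opts = brute_force_optimal(inst)
        for members in oracle_class_groups("E", opts).values():
            assert len({event_vector(m, inst) for m in members}) == 1

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("cv", TEST_COSTS)
    def test_event_support_matches_oracle(self, seed, cv):
        inst = random_instance(4, 4, seed, costs=parse_cost_vector(cv))
        _, opts = brute_force_optimal(inst)
        g = build_graph(inst)
        sup = event_support(g)
        assert sup.total == len(opts)
        assert sup.counts == oracle_support(opts)
        # cross-check the aggregated pass against class-relaxed pruning
        P = inst.parasite
        for p in inst.internal_parasites:
            for e, expected in sup.counts[p].items():
                by_pruning = sum(
                    class_info(g, ca, "count")
                    for ca, _ in enumerate_classes(g, "E")
                    if ca.payload(p) == e
                )
                assert by_pruning == expected
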