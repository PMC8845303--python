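from fractions import Fraction

import pytest

from reconspace import (
    brute_force_optimal,
    classify_event,
    enumerate_all_valid,
    event_vector,
    loss_contribution,
    parse_cost_vector,
    reconciliation_cost,
    toy12,
    validate_reconciliation,
)
from reconspace.fixtures import random_instance
from reconspace.model import InfeasibleError, Reconciliation


def _ids(inst):
    P, H = inst.parasite, inst.host
    return (
        {P.name[v]: v for v in range(len(P))},
        {H.name[v]: v for v in range(len(H))},
    )


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "h,h1,h2,expected",
        [
            ("hx", "hb", "hc", "C"),  # strict meet of incomparable children
            ("hb", "hb", "hc", "S"),  # one child stays, the other jumps
            ("hr", "hb", "hc", "D"),  # meet below the node: duplication
            ("ha", "hb", "hc", None),  # both children incomparable: invalid
            ("hr", "hr", "ha", "D"),  # comparable children: catch-all duplication
            ("hx", "hx", "ha", "S"),  # descendant includes the node itself
        ],
    )
    def test_case_analysis(self, toy, h, h1, h2, expected):
        _, H = _ids(toy)
        assert classify_event(toy.hidx, H[h], H[h1], H[h2]) == expected

    def test_exhaustive_and_exclusive(self, toy):
        # exactly one of {C, D, S, None} for every host triple
        n = len(toy.host)
        for h in range(n):
            for h1 in range(n):
                for h2 in range(n):
                    e = classify_event(toy.hidx, h, h1, h2)
                    assert e in ("C", "D", "S", None)


class TestLossContribution:
    @pytest.mark.parametrize(
        "h,h1,h2,expected",
        [
            ("hx", "hb", "hc", 0),  # cospeciation: d+d-2
            ("hr", "hb", "hc", 4),  # duplication: d+d
            ("hx", "hb", "ha", 1),  # switch: arcs on the descendant side only
            ("hr", "hr", "ha", 1),  # duplication with one child in place
        ],
    )
    def test_rows(self, toy, h, h1, h2, expected):
        _, H = _ids(toy)
        assert loss_contribution(toy.hidx, H[h], H[h1], H[h2]) == expected

    def test_invalid_triple_rejected(self, toy):
        _, H = _ids(toy)
        with pytest.raises(ValueError):
            loss_contribution(toy.hidx, H["ha"], H["hb"], H["hc"])


class TestValidation:
    def _phi(self, toy, p1_host, p0_host):
        P, H = _ids(toy)
        toy_sigma = toy.sigma
        d = {p: (toy_sigma[p], "T") for p in toy.parasite.leaves}
        hidx = toy.hidx
        for name, h in (("p1", p1_host), ("p0", p0_host)):
            p = P[name]
            c1, c2 = toy.parasite.children[p]
            e = classify_event(hidx, H[h], d[c1][0] if c1 in d else None, d[c2][0])
            d[p] = (H[h], e)
        return Reconciliation.from_dict(d)

    def test_all_cospeciation_solution_valid(self, toy):
        phi = self._phi(toy, "hx", "hr")
        rep = validate_reconciliation(phi, toy)
        assert rep.valid
        assert event_vector(phi, toy) == (2, 0, 0, 0)

    def test_invalid_internal_placement(self, toy):
        P, H = _ids(toy)
        d = {p: (toy.sigma[p], "T") for p in toy.parasite.leaves}
        d[P["p1"]] = (H["ha"], "D")  # both children incomparable to ha
        d[P["p0"]] = (H["hr"], "C")
        rep = validate_reconciliation(Reconciliation.from_dict(d), toy)
        assert not rep.valid
        assert any(node == "p1" for node, _ in rep.violations)

    def test_leaf_off_sigma_invalid(self, toy):
        P, H = _ids(toy)
        d = {p: (toy.sigma[p], "T") for p in toy.parasite.leaves}
        d[P["pa"]] = (H["ha"], "T")  # sigma says hb
        d[P["p1"]] = (H["hr"], "D")
        d[P["p0"]] = (H["hr"], "D")
        rep = validate_reconciliation(Reconciliation.from_dict(d), toy)
        assert not rep.valid


class TestEventVectorAndCost:
    def test_switch_solution_vector(self, toy):
        phi = self._switch_solution(toy)
        assert event_vector(phi, toy) == (1, 0, 1, 1)
        assert reconciliation_cost((1, 0, 1, 1), (0, 1, 1, 1)) == 2
        assert reconciliation_cost((2, 0, 0, 0), (0, 1, 1, 1)) == 0

    def _switch_solution(self, toy):
        P, H = _ids(toy)
        d = {p: (toy.sigma[p], "T") for p in toy.parasite.leaves}
        d[P["p1"]] = (H["hb"], "S")
        d[P["p0"]] = (H["hr"], "C")
        return Reconciliation.from_dict(d)

    def test_zero_cost_vector_makes_everything_optimal(self, toy, toy_optima):
        cost, opts = toy_optima
        assert cost == 0
        assert len(opts) == 12
        assert all(
            reconciliation_cost(event_vector(p, toy), toy.costs) == 0 for p in opts
        )

    def test_cost_parsing_exact_rationals(self):
        assert parse_cost_vector("-1,1,1,1") == (-1, 1, 1, 1)
        assert parse_cost_vector("0.5, 1, 2, 0.25") == (
            Fraction(1, 2), 1, 2, Fraction(1, 4))
        with pytest.raises(ValueError):
            parse_cost_vector("1,2,3")


class TestOracle:
    def test_toy_has_exactly_12_valid_reconciliations(self, toy, toy_optima):
        all_valid = list(enumerate_all_valid(toy))
        assert len(all_valid) == 12
        assert len(set(all_valid)) == 12
        _, opts = toy_optima
        assert set(all_valid) == set(opts)

    def test_single_leaf_instance(self):
        inst = random_instance(1, 1, seed=0)
        sols = list(enumerate_all_valid(inst))
        assert len(sols) == 1
        assert event_vector(sols[0], inst) == (0, 0, 0, 0)

    @pytest.mark.parametrize(
        "cv,cost,n_opt",
        [("0,0,0,0", 0, 12), ("0,1,1,1", 0, 1), ("-1,1,1,1", -2, 1)],
    )
    def test_optimal_filtering(self, cv, cost, n_opt):
        inst = toy12(parse_cost_vector(cv))
        best, opts = brute_force_optimal(inst)
        assert best == cost
        assert len(opts) == n_opt

    def test_event_sum_and_loss_bound_invariants(self):
        # first three vector entries always sum to the internal-node count;
        # per-reconciliation losses stay under the diameter bound
        for seed in range(10):
            inst = random_instance(4, 4, seed)
            internal = len(inst.internal_parasites)
            bound = internal * 2 * inst.hidx.diameter()
            for phi in enumerate_all_valid(inst):
                v = event_vector(phi, inst)
                assert v[0] + v[1] + v[2] == internal
                assert 0 <= v[3] <= bound

    def test_infeasible_error_requires_no_valid_reconciliation(self):
        # mapping every internal parasite to the host root is always valid,
        # so brute force must never report infeasible on a well-formed instance
        for seed in range(5):
            inst = random_instance(3, 3, seed)
            best, opts = brute_force_optimal(inst)
            assert opts
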