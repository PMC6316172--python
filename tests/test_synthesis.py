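"""Synthesis engine vs exhaustive enumeration, and its characterisation ops.

The brute-force oracle simulates every concrete model directly through the
network-core dynamics; the SAT route must agree exactly on satisfiability,
model counts and required/disallowed/used classifications.
"""

import random

import pytest

from abnet.bruteforce import (brute_classify, brute_conditions_used,
                              brute_count, brute_satisfiable,
                              consistent_models)
from abnet.constraints import (Expectation, REACHED, NEVER, check_constraint,
                               experiment, partial_state)
from abnet.network import (AbstractNetwork, Component, ConcreteModel,
                           Interaction)
from abnet.synthesis import (SATISFIABLE, UNSATISFIABLE, classify_conditions,
                             classify_interactions, component_deletion_scan,
                             count_models, minimal_model, random_abn_control,
                             synthesize)
from tests.conftest import random_instance


def two_gene_net(allowed=frozenset(range(9))):
    comps = [Component("A", allowed_conditions=allowed),
             Component("B", allowed_conditions=allowed)]
    edge = Interaction("A", "B", True, False)
    return AbstractNetwork(comps, [edge]), edge


class TestSynthesize:
    def test_single_optional_edge_instantiated_when_needed(self):
        net, edge = two_gene_net()
        con = experiment("e", {}, {"A": True, "B": False},
                         [Expectation(REACHED, partial_state({"B": True}),
                                      1, 1)],
                         clamps=[], bound=2)
        res = synthesize(net, [con])
        assert res.status == SATISFIABLE
        assert edge in res.witness.chosen_optional

    def test_contradictory_expectations_unsatisfiable(self):
        net, _ = two_gene_net()
        con = experiment("e", {}, {"A": True, "B": False}, [
            Expectation(NEVER, partial_state({"B": True})),
            Expectation(REACHED, partial_state({"B": True}), 1, 1),
        ], bound=5)
        assert synthesize(net, [con]).status == UNSATISFIABLE

    def test_witness_verified_by_simulation(self, rng):
        for _ in range(20):
            net, cons = random_instance(rng)
            res = synthesize(net, cons)
            if res.satisfiable:
                assert all(check_constraint(res.witness, c) for c in cons)


class TestOracleEquivalence:
    def test_random_instances_match_bruteforce(self, rng):
        for _ in range(60):
            net, cons = random_instance(rng)
            res = synthesize(net, cons, timeout=60)
            assert res.status in (SATISFIABLE, UNSATISFIABLE)
            assert res.satisfiable == brute_satisfiable(net, cons)
            if not res.satisfiable:
                continue
            assert count_models(net, cons).count == brute_count(net, cons)
            req, dis, _ = brute_classify(net, cons)
            cls = classify_interactions(net, cons, result=res)
            assert set(cls.required) == req
            assert set(cls.disallowed) == dis
            assert classify_conditions(net, cons, result=res) == \
                brute_conditions_used(net, cons)


class TestCounting:
    def test_unconstrained_count_is_power_of_two(self):
        comps = [Component("A", allowed_conditions=frozenset({8})),
                 Component("B", allowed_conditions=frozenset({8}))]
        edges = [Interaction("A", "B", True, False),
                 Interaction("B", "A", True, False),
                 Interaction("A", "B", False, False)]
        net = AbstractNetwork(comps, edges)
        assert count_models(net, []).count == 2 ** 3

    def test_contradiction_counts_zero(self):
        net, _ = two_gene_net()
        con = experiment("e", {}, {"A": True, "B": False}, [
            Expectation(NEVER, partial_state({"B": True})),
            Expectation(REACHED, partial_state({"B": True}), 1, 1)],
            bound=4)
        assert count_models(net, [con]).count == 0

    def test_cap_reported(self):
        comps = [Component(f"G{i}", allowed_conditions=frozenset({8}))
                 for i in range(3)]
        edges = [Interaction("G0", "G1", True, False),
                 Interaction("G0", "G2", True, False),
                 Interaction("G1", "G2", True, False)]
        net = AbstractNetwork(comps, edges)
        mc = count_models(net, [], cap=3)
        assert mc.cap_exceeded and mc.count == 3


class TestMinimalModel:
    def test_matches_bruteforce_minimum(self, rng):
        found = 0
        while found < 12:
            net, cons = random_instance(rng)
            models = consistent_models(net, cons)
            if not models:
                continue
            found += 1
            best = min(m.n_interactions() for m in models)
            assert minimal_model(net, cons).n_interactions() == best

    def test_all_definite_network_returned_as_is(self):
        comps = [Component("A", allowed_conditions=frozenset({8}))]
        net = AbstractNetwork(comps, [])
        m = minimal_model(net, [])
        assert m.chosen_optional == frozenset()


class TestClassification:
    def test_empty_constraints_nothing_required_or_disallowed(self):
        net, _ = two_gene_net()
        cls = classify_interactions(net, [])
        assert cls.required == [] and cls.disallowed == []

    def test_single_allowed_condition_reported_used(self):
        comps = [Component("A", allowed_conditions=frozenset({4}))]
        net = AbstractNetwork(comps, [])
        assert classify_conditions(net, []) == {"A": {4: "used"}}

    def test_adding_constraints_never_shrinks_required_set(self, rng):
        checked = 0
        while checked < 10:
            net, cons = random_instance(rng, max_constraints=2)
            if len(cons) < 2:
                continue
            try:
                c1 = classify_interactions(net, cons[:1])
                c2 = classify_interactions(net, cons)
            except ValueError:
                continue
            checked += 1
            assert set(c1.required) <= set(c2.required)
            assert set(c1.disallowed) <= set(c2.disallowed)


class TestControls:
    def test_deletion_scan_toy(self):
        # B's activation evidence hinges on A; deleting C is harmless
        comps = [Component(n, allowed_conditions=frozenset({8}))
                 for n in "ABC"]
        net = AbstractNetwork(comps, [Interaction("A", "B", True, True)])
        con = experiment("e", {}, {"A": True, "B": False, "C": False},
                         [Expectation(REACHED, partial_state({"B": True}),
                                      1, 1)], bound=2)
        scan = component_deletion_scan(net, [con])
        assert scan["C"] == SATISFIABLE
        assert scan["A"] == UNSATISFIABLE

    def test_deletion_scan_refuses_signals(self):
        comps = [Component("L", "signal"), Component("A")]
        net = AbstractNetwork(comps, [Interaction("L", "A", True, True)])
        with pytest.raises(ValueError):
            net.without_component("L")

    def test_random_control_reproducible_and_counted(self):
        net, _ = two_gene_net(allowed=frozenset({8}))
        r1 = random_abn_control(net, [], n_models=15, seed=5)
        r2 = random_abn_control(net, [], n_models=15, seed=5)
        assert r1 == r2
        # empty constraints: every sampled ABN is satisfiable
        assert r1["n_satisfiable"] == 15
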