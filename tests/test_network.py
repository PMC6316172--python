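import itertools
import random

import pytest

from abnet.network import (ALL, NONE, REGULATION_CONDITIONS, SOME,
                           AbstractNetwork, Clamp, Component, ConcreteModel,
                           Interaction, PerturbationSchedule,
                           enumerate_regulation_conditions,
                           evaluate_condition, sync_step, sync_trajectory)

LEVELS = (NONE, SOME, ALL)


class TestRegulationConditions:
    def test_exactly_nine(self):
        assert len(enumerate_regulation_conditions()) == 9

    def test_matches_bruteforce_enumeration(self):
        # independently enumerate all 2^9 tables and filter by the defining
        # properties: no-activator row False, True at (all, none), monotone
        cells = [(a, r) for a in LEVELS for r in LEVELS]
        valid = []
        for bits in itertools.product([False, True], repeat=9):
            t = dict(zip(cells, bits))
            if any(t[(NONE, r)] for r in LEVELS):
                continue
            if not t[(ALL, NONE)]:
                continue
            mono = all(t[(a, r)] <= t[(a2, r)]
                       for a in LEVELS for a2 in LEVELS if a <= a2
                       for r in LEVELS) and \
                   all(t[(a, r)] >= t[(a, r2)]
                       for r in LEVELS for r2 in LEVELS if r <= r2
                       for a in LEVELS)
            if mono:
                valid.append(t)
        assert len(valid) == 9
        ours = [dict(c.table) for c in REGULATION_CONDITIONS]
        assert all(t in ours for t in valid)

    def test_ordering_least_to_most_permissive(self):
        counts = [c.n_true() for c in REGULATION_CONDITIONS]
        assert counts == sorted(counts)
        assert REGULATION_CONDITIONS[0].n_true() == 1
        assert REGULATION_CONDITIONS[0].table[(ALL, NONE)] is True

    def test_no_activator_means_off(self):
        for c in REGULATION_CONDITIONS:
            for r in LEVELS:
                assert c.table[(NONE, r)] is False
            assert evaluate_condition(c, 0, 3, 1, 2) is False
            assert evaluate_condition(c, 0, 0, 0, 0) is False

    def test_all_activators_no_repressors_always_on(self):
        for c in REGULATION_CONDITIONS:
            assert evaluate_condition(c, 2, 2, 0, 0) is True

    def test_most_permissive_on_despite_full_repression(self):
        assert evaluate_condition(REGULATION_CONDITIONS[8], 1, 3, 3, 3) is True

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate_condition(REGULATION_CONDITIONS[0], -1, 2, 0, 0)
        with pytest.raises(ValueError):
            evaluate_condition(REGULATION_CONDITIONS[0], 3, 2, 0, 0)


def chain_model(edges, conditions=None, comps=None):
    names = sorted({n for e in edges for n in e[:2]} | set(comps or []))
    net = AbstractNetwork(
        [Component(n) for n in names],
        [Interaction(s, t, pos, True) for s, t, pos in edges])
    conds = {n: 8 for n in names}
    conds.update(conditions or {})
    return ConcreteModel(net, frozenset(), conds)


class TestSyncDynamics:
    def test_no_interactions_all_low_is_fixed_point(self):
        m = chain_model([], comps=["A", "B"])
        state = {"A": False, "B": False}
        assert sync_step(m, state) == state

    def test_single_positive_edge_propagates(self):
        m = chain_model([("A", "B", True)])
        sched = PerturbationSchedule(clamps=(Clamp("A", True),))
        nxt = sync_step(m, {"A": True, "B": False}, sched)
        assert nxt["B"] is True

    def test_condition0_blocks_on_any_repression(self):
        # A -> B and C -| B with the strictest condition: (all, all) is False
        m = chain_model([("A", "B", True), ("C", "B", False)],
                        conditions={"B": 0})
        sched = PerturbationSchedule(clamps=(Clamp("A", True),
                                             Clamp("C", True)))
        nxt = sync_step(m, {"A": True, "B": False, "C": True}, sched)
        assert nxt["B"] is False

    def test_unknown_component_rejected(self):
        m = chain_model([("A", "B", True)])
        with pytest.raises(ValueError):
            sync_step(m, {"A": True, "B": False, "Z": True})

    def test_mutual_activation_all_high_is_stable(self):
        m = chain_model([("A", "B", True), ("B", "A", True)])
        states, fixed = sync_trajectory(m, {"A": True, "B": True}, bound=5)
        assert fixed
        assert all(s == {"A": True, "B": True} for s in states)

    def test_deterministic_replay(self):
        m = chain_model([("A", "B", True), ("B", "C", True),
                         ("C", "A", False)], conditions={"A": 2})
        sched = PerturbationSchedule(clamps=(Clamp("B", True, 1, 3),))
        t1 = sync_trajectory(m, {"A": True}, sched, bound=8)
        t2 = sync_trajectory(m, {"A": True}, sched, bound=8)
        assert t1 == t2

    def test_sync_step_is_pure(self):
        m = chain_model([("A", "B", True)])
        state = {"A": True, "B": False}
        first = sync_step(m, state)
        assert sync_step(m, state) == first
        assert state == {"A": True, "B": False}  # input untouched

    def test_trajectory_enters_cycle_within_state_space_bound(self, rng):
        # with m components, any synchronous trajectory must revisit a state
        # within 2^m steps
        from tests.conftest import random_instance
        for _ in range(10):
            net, _ = random_instance(rng, max_components=4)
            conds = {g.name: min(g.allowed_conditions) for g in net.genes}
            model = ConcreteModel(net, frozenset(net.optional_interactions),
                                  conds)
            m = len(net.components)
            initial = {c.name: rng.random() < 0.5 for c in net.components}
            states, _ = sync_trajectory(model, initial, bound=2 ** m + 1)
            seen = set()
            cycled = False
            for s in states:
                key = tuple(sorted(s.items()))
                if key in seen:
                    cycled = True
                    break
                seen.add(key)
            assert cycled

    def test_uninstantiated_optional_edge_is_inert(self, rng):
        from tests.conftest import random_instance
        for _ in range(10):
            net, _ = random_instance(rng)
            if not net.optional_interactions:
                continue
            conds = {g.name: min(g.allowed_conditions) for g in net.genes}
            base = ConcreteModel(net, frozenset(), conds)
            # same chosen set, but network stripped of optional interactions
            stripped = AbstractNetwork(net.components,
                                       net.definite_interactions)
            ref = ConcreteModel(stripped, frozenset(), conds)
            initial = {c.name: rng.random() < 0.5 for c in net.components}
            assert sync_trajectory(base, initial, bound=6) == \
                sync_trajectory(ref, initial, bound=6)


class TestStructuralValidation:
    def test_duplicate_component_rejected(self):
        with pytest.raises(ValueError):
            AbstractNetwork([Component("A"), Component("A")], [])

    def test_signal_target_rejected(self):
        comps = [Component("L", "signal"), Component("A")]
        with pytest.raises(ValueError):
            AbstractNetwork(comps, [Interaction("A", "L", True, True)])

    def test_gene_needs_allowed_condition(self):
        with pytest.raises(ValueError):
            Component("A", allowed_conditions=frozenset())

    def test_condition_assignment_validated(self):
        net = AbstractNetwork(
            [Component("A", allowed_conditions=frozenset({0, 1}))], [])
        with pytest.raises(ValueError):
            ConcreteModel(net, frozenset(), {"A": 5})

    def test_clamp_window(self):
        sched = PerturbationSchedule(clamps=(Clamp("A", True, 2, 4),))
        assert sched.clamp_value("A", 1) is None
        assert sched.clamp_value("A", 2) is True
        assert sched.clamp_value("A", 4) is True
        assert sched.clamp_value("A", 5) is None
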