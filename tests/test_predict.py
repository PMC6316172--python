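"""Prediction engine: backend agreement, trichotomy, soundness, scoring."""

import random

import pytest

from abnet.network import (AbstractNetwork, Clamp, Component, Interaction,
                           PerturbationSchedule)
from abnet.predict import (NEGATIVE, NO_PREDICTION, POSITIVE, OutcomeRow,
                           Prediction, PredictionEngine, run_battery,
                           score_predictions)
from abnet.synthetic import generate_observations, sample_ground_truth
from tests.conftest import random_instance


def small_cabn(rng):
    """A random instance with a satisfiable constraint set."""
    while True:
        net, cons = random_instance(rng, max_components=3, max_optional=4)
        from abnet.bruteforce import brute_satisfiable
        if brute_satisfiable(net, cons):
            return net, cons


def engines(net, cons):
    return (PredictionEngine(net, cons, strategy="brute"),
            PredictionEngine(net, cons, strategy="sat", timeout=60))


class TestBackendAgreement:
    """The enumerative (simulation) and SAT backends implement the same
    query semantics; on small instances they must agree exactly."""

    def test_steps_and_activation_queries(self, rng):
        for _ in range(8):
            net, cons = small_cabn(rng)
            brute, sat = engines(net, cons)
            names = [c.name for c in net.genes]
            sched = PerturbationSchedule()
            initial = {n: rng.random() < 0.5 for n in names}
            target = {n: True for n in rng.sample(names, 1)}
            assert brute.steps_to_target(sched, initial, target, bound=6) == \
                sat.steps_to_target(sched, initial, target, bound=6)
            gene = rng.choice(names)
            assert brute.activation_step(gene, sched, initial, bound=6) == \
                sat.activation_step(gene, sched, initial, bound=6)

    def test_ordering_and_perturbation_queries(self, rng):
        for _ in range(8):
            net, cons = small_cabn(rng)
            brute, sat = engines(net, cons)
            names = [c.name for c in net.genes]
            sched = PerturbationSchedule()
            initial = {n: rng.random() < 0.5 for n in names}
            target = {n: True for n in rng.sample(names, 1)}
            if len(names) >= 2:
                x, y = rng.sample(names, 2)
                assert brute.precedes(x, y, sched, initial, bound=6) == \
                    sat.precedes(x, y, sched, initial, bound=6)
            comp = rng.choice(names)
            assert brute.essentiality(comp, sched, initial, target, 6) == \
                sat.essentiality(comp, sched, initial, target, 6)
            forced = sched.with_clamp(rng.choice(names), True)
            for mode in ("first_hit", "first_stable"):
                assert brute.compare_schedules(forced, sched, initial,
                                               target, 6, mode=mode) == \
                    sat.compare_schedules(forced, sched, initial, target,
                                          6, mode=mode)


class TestQuerySemantics:
    def chain(self):
        comps = [Component(n, allowed_conditions=frozenset({8}))
                 for n in ("A", "B", "C")]
        edges = [Interaction("A", "B", True, True),
                 Interaction("B", "C", True, True)]
        net = AbstractNetwork(comps, edges)
        return net

    def test_cascade_steps_to_target(self):
        net = self.chain()
        eng = PredictionEngine(net, [], strategy="brute")
        sched = PerturbationSchedule(clamps=(Clamp("A", True),))
        res = eng.steps_to_target(sched, {"A": True}, {"C": True}, bound=6)
        # C switches on at step 2 and stays: a single model, so some == all
        assert res["step_some"] == res["step_all"] == 2

    def test_forced_gene_precedes_everything(self):
        net = self.chain()
        eng = PredictionEngine(net, [], strategy="brute")
        sched = PerturbationSchedule(clamps=(Clamp("A", True),))
        out = eng.precedes("A", "C", sched, {"A": True}, bound=6)
        assert out["outcome"] == "always_before"
        rev = eng.precedes("C", "A", sched, {"A": True}, bound=6)
        assert rev["outcome"] == "never_before"

    def test_identical_schedules_compare_equivalent(self):
        net = self.chain()
        eng = PredictionEngine(net, [], strategy="brute")
        sched = PerturbationSchedule(clamps=(Clamp("A", True),))
        out = eng.compare_schedules(sched, sched, {"A": True}, {"C": True},
                                    bound=6)
        assert out["outcome"] == "equivalent"
        assert out["a_never_slower"] and out["b_never_slower"]

    def test_upstream_activator_is_essential(self):
        net = self.chain()
        eng = PredictionEngine(net, [], strategy="brute")
        sched = PerturbationSchedule(clamps=(Clamp("A", True),))
        out = eng.essentiality("B", sched, {"A": True}, {"C": True}, 6)
        assert out["outcome"] == "required"

    def test_cocktail_covers_target_when_clamped(self):
        net = self.chain()
        eng = PredictionEngine(net, [], strategy="brute")
        out = eng.cocktail_outcome(["A"], {}, {"B": True, "C": True}, bound=6)
        assert out["outcome"] == "reprograms"
        empty = eng.cocktail_outcome([], {}, {"C": True}, bound=6)
        assert empty["outcome"] == "fails"

    def test_unknown_cocktail_factor_ignored_with_warning(self, caplog):
        net = self.chain()
        eng = PredictionEngine(net, [], strategy="brute")
        import logging
        with caplog.at_level(logging.WARNING, logger="abnet.predict"):
            out = eng.cocktail_outcome(["A", "cMyc"], {}, {"B": True},
                                       bound=4)
        assert out["ignored"] == ["cMyc"]
        assert "cMyc" in caplog.text

    def test_essentiality_refuses_signals(self):
        comps = [Component("L", "signal"),
                 Component("A", allowed_conditions=frozenset({8}))]
        net = AbstractNetwork(comps, [Interaction("L", "A", True, True)])
        eng = PredictionEngine(net, [], strategy="brute")
        with pytest.raises(ValueError):
            eng.essentiality("L", PerturbationSchedule(), {}, {"A": True})


class TestSoundness:
    def test_definitive_predictions_never_contradict_ground_truth(self):
        for seed in (0, 1, 2):
            gt = sample_ground_truth(6, 3, 10, seed=50 + seed,
                                     conditions_per_gene=2)
            cons, heldout = generate_observations(gt, seed=seed)
            eng = PredictionEngine(gt.network, cons, strategy="brute")
            # ground truth itself is in the consistent set
            assert any(m.chosen_optional == gt.model.chosen_optional
                       and dict(m.conditions) == dict(gt.model.conditions)
                       for m in eng.models)
            for q in heldout:
                verdict = eng.reach_and_hold(q.schedule, q.initial, q.target)
                if verdict == POSITIVE:
                    assert q.observed
                elif verdict == NEGATIVE:
                    assert not q.observed

    def test_outcome_trichotomy(self, rng):
        for _ in range(5):
            net, cons = small_cabn(rng)
            eng = PredictionEngine(net, cons, strategy="brute")
            names = [c.name for c in net.genes]
            target = {rng.choice(names): True}
            verdict = eng.reach_and_hold(PerturbationSchedule(),
                                         {n: False for n in names}, target, 6)
            assert verdict in (POSITIVE, NEGATIVE, NO_PREDICTION)


class TestBattery:
    def test_battery_runs_every_query_kind(self):
        comps = [Component(n, allowed_conditions=frozenset({8}))
                 for n in ("A", "B")]
        net = AbstractNetwork(comps, [Interaction("A", "B", True, True)])
        eng = PredictionEngine(net, [], strategy="brute")
        battery = [
            {"name": "q1", "type": "reach_and_hold",
             "clamps": [["A", "high"]], "initial": {"A": True},
             "target": {"B": True}, "bound": 5},
            {"name": "q2", "type": "steps_to_target",
             "clamps": [["A", "high"]], "initial": {"A": True},
             "target": {"B": True}, "bound": 5},
            {"name": "q3", "type": "activation_step", "gene": "B",
             "clamps": [["A", "high"]], "initial": {"A": True}, "bound": 5},
            {"name": "q4", "type": "precedes", "gene_x": "A", "gene_y": "B",
             "clamps": [["A", "high"]], "initial": {"A": True}, "bound": 5},
            {"name": "q5", "type": "essentiality", "gene": "A",
             "clamps": [], "initial": {"A": True}, "target": {"B": True},
             "bound": 5},
            {"name": "q6", "type": "cocktail", "cocktail": ["A"],
             "target": {"B": True}, "bound": 5},
        ]
        preds = run_battery(eng, battery)
        assert [p.query for p in preds] == [q["name"] for q in battery]
        assert all(p.outcome in (POSITIVE, NEGATIVE, NO_PREDICTION)
                   for p in preds)


class TestScoring:
    def test_all_correct_scores_one(self):
        preds = [Prediction("a", POSITIVE), Prediction("b", NEGATIVE)]
        rows = [OutcomeRow("a", "supports-positive"),
                OutcomeRow("b", "supports-negative")]
        rep = score_predictions(preds, rows)
        assert rep["accuracy"] == 1.0
        assert rep["conservative_accuracy"] == 1.0
        assert rep["unmapped"] == []

    def test_no_prediction_counts_only_conservatively(self):
        preds = [Prediction("a", POSITIVE), Prediction("b", NO_PREDICTION)]
        rows = [OutcomeRow("a", "supports-positive"),
                OutcomeRow("b", "supports-positive")]
        rep = score_predictions(preds, rows)
        assert rep["accuracy"] == 1.0
        assert rep["conservative_accuracy"] == 0.5
        assert rep["n_no_prediction"] == 1

    def test_unmapped_rows_reported_not_dropped(self):
        rep = score_predictions([Prediction("a", POSITIVE)],
                                [OutcomeRow("a", "supports-negative"),
                                 OutcomeRow("zzz", "supports-positive")])
        assert rep["unmapped"] == ["zzz"]
        assert rep["accuracy"] == 0.0
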