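"""All-models predictions over a constrained abstract Boolean network.

A prediction is formulated by testing a hypothesis about an untested
experiment against the full set of consistent models, together with its null:

* hypothesis holds in every model   -> a *positive* prediction;
* hypothesis holds in no model      -> a *negative* prediction;
* the model set disagrees           -> *no prediction* (and a discriminating
  experiment that would further constrain the model set).

Two interchangeable backends answer queries:

``enumerate``
    The consistent-model set is enumerated once (blocking-clause iteration);
    each query then simulates every model's deterministic trajectory.  Exact
    and fast per query when the set fits in memory.
``sat``
    Hypotheses are reified in the shared CNF unrolling and tested as solver
    assumptions (hypothesis satisfiable? null satisfiable?).  Scales past
    enumerable model sets.

``strategy="auto"`` tries enumeration up to a cap and falls back to SAT.
``strategy="brute"`` enumerates by exhaustive simulation instead of through
the solver -- a fully solver-independent route for small networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .constraints import Constraint, encode_constraints
from .encoding import SynthesisEncoder, Trajectory
from .network import (AbstractNetwork, Clamp, ConcreteModel,
                      PerturbationSchedule, SIGNAL, State, apply_schedule,
                      sync_step)

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
NO_PREDICTION = "no_prediction"


@dataclass
class Prediction:
    query: str
    outcome: str
    details: Dict[str, object] = field(default_factory=dict)


class QueryError(RuntimeError):
    pass


def _schedule_key(schedule: PerturbationSchedule, initial: Mapping[str, bool],
                  bound: int) -> tuple:
    return (tuple(sorted(schedule.inputs.items())),
            tuple(schedule.clamps),
            tuple(sorted(initial.items())), bound)


def _matches(state: Mapping[str, bool], partial: Mapping[str, bool]) -> bool:
    return all(state[k] == v for k, v in partial.items())


# ---------------------------------------------------------------------------
# Simulation-side query primitives (exact on one concrete model)
# ---------------------------------------------------------------------------

def simulate_states(model: ConcreteModel, schedule: PerturbationSchedule,
                    initial: Mapping[str, bool], bound: int) -> List[State]:
    """States 0 .. bound+1 (the extra step probes stability)."""
    states = [apply_schedule(model, initial, schedule, 0)]
    for t in range(bound + 1):
        states.append(sync_step(model, states[-1], schedule, t))
    return states


def stabilisation_step(states: List[State], target: Mapping[str, bool],
                       bound: int) -> Optional[int]:
    """Smallest s with the target holding on [s, bound+1] and the final
    state a fixed point; None if the trajectory does not settle there."""
    if states[bound] != states[bound + 1]:
        return None
    s = bound + 1
    while s > 0 and _matches(states[s - 1], target):
        s -= 1
    return s if s <= bound and _matches(states[bound + 1], target) else None


def permanent_activation_step(states: List[State], gene: str,
                              bound: int) -> Optional[int]:
    """Smallest s with the gene High on [s, bound+1]; None if never."""
    if not states[bound + 1][gene]:
        return None
    s = bound + 1
    while s > 0 and states[s - 1][gene]:
        s -= 1
    return s if s <= bound else None


def first_hit_step(states: List[State], target: Mapping[str, bool],
                   bound: int) -> Optional[int]:
    for t in range(bound + 1):
        if _matches(states[t], target):
            return t
    return None


class PredictionEngine:
    """Query battery over the cABN defined by a network and its constraints.

    ``strategy``: "enumerate", "sat" or "auto" (enumerate up to
    ``enumeration_cap`` models, falling back to the SAT backend).
    """

    def __init__(self, network: AbstractNetwork,
                 constraints: Sequence[Constraint],
                 timeout: float = 300.0,
                 strategy: str = "auto",
                 enumeration_cap: int = 20000):
        if strategy not in ("auto", "enumerate", "sat", "brute"):
            raise ValueError(f"unknown strategy {strategy!r}")
        self.network = network
        self.constraints = tuple(constraints)
        self.timeout = timeout
        self.models: Optional[List[ConcreteModel]] = None
        self.encoder: Optional[SynthesisEncoder] = None
        self._trajs: Dict[tuple, Trajectory] = {}
        self._sim_cache: Dict[tuple, List[State]] = {}
        self._n_traj = 0
        if strategy == "brute":
            from .bruteforce import consistent_models
            self.models = consistent_models(network, constraints)
            if not self.models:
                raise QueryError("base constraints unsatisfiable")
        if strategy in ("auto", "enumerate"):
            from .synthesis import count_models
            try:
                mc = count_models(network, constraints, cap=enumeration_cap,
                                  timeout=timeout, keep_models=True)
            except TimeoutError:
                mc = None
            if mc is not None and not mc.cap_exceeded:
                if mc.count == 0:
                    raise QueryError("base constraints unsatisfiable")
                self.models = mc.models
                logger.info("enumerated %d consistent models", mc.count)
            elif strategy == "enumerate":
                raise QueryError(
                    f"consistent-model set exceeds cap {enumeration_cap}")
        if self.models is None:
            self.encoder = SynthesisEncoder(network)
            encode_constraints(self.encoder, self.constraints)
            if self._solve([]) is not True:
                raise QueryError("base constraints not satisfiable")

    @property
    def backend(self) -> str:
        return "enumerate" if self.models is not None else "sat"

    # -- SAT internals ------------------------------------------------------
    def _solve(self, assumptions: Sequence[int]) -> Optional[bool]:
        res = self.encoder.solver.solve(assumptions=assumptions,
                                        time_budget=self.timeout)
        if res is None:
            raise QueryError("solver budget exhausted; result indeterminate")
        return res

    def trajectory(self, schedule: PerturbationSchedule,
                   initial: Mapping[str, bool], bound: int = 20) -> Trajectory:
        key = _schedule_key(schedule, initial, bound)
        traj = self._trajs.get(key)
        if traj is None:
            self._n_traj += 1
            traj = self.encoder.add_trajectory(f"query{self._n_traj}",
                                               schedule, initial, bound)
            self._trajs[key] = traj
        return traj

    def _decide_lit(self, hypothesis_lit: int) -> str:
        hyp = self._solve([hypothesis_lit])
        null = self._solve([-hypothesis_lit])
        if hyp and not null:
            return POSITIVE
        if null and not hyp:
            return NEGATIVE
        if hyp and null:
            return NO_PREDICTION
        raise QueryError("hypothesis and null both unsatisfiable: "
                         "query inconsistent with the base constraints")

    # -- enumerative internals ----------------------------------------------
    def _states(self, model_idx: int, schedule: PerturbationSchedule,
                initial: Mapping[str, bool], bound: int) -> List[State]:
        key = (model_idx,) + _schedule_key(schedule, initial, bound)
        st = self._sim_cache.get(key)
        if st is None:
            st = simulate_states(self.models[model_idx], schedule, initial,
                                 bound)
            self._sim_cache[key] = st
        return st

    @staticmethod
    def _decide_bools(values: Sequence[bool]) -> str:
        if all(values):
            return POSITIVE
        if not any(values):
            return NEGATIVE
        return NO_PREDICTION

    # -- step queries --------------------------------------------------------
    def steps_to_target(self, schedule: PerturbationSchedule,
                        initial: Mapping[str, bool],
                        target: Mapping[str, bool],
                        bound: int = 20) -> Dict[str, object]:
        """Earliest step at which some model, and at which every model, has
        stabilised in the target state ("stabilised at s" = target holds
        from s to the bound and the final state is a fixed point).

        ``step_some``/``step_all`` are None when no / not every model ever
        stabilises within the bound.
        """
        if self.models is not None:
            steps = [stabilisation_step(
                self._states(i, schedule, initial, bound), dict(target), bound)
                for i in range(len(self.models))]
            reached = [s for s in steps if s is not None]
            return {"step_some": min(reached) if reached else None,
                    "step_all": (max(steps) if all(s is not None
                                                   for s in steps) else None),
                    "bound": bound}
        traj = self.trajectory(schedule, initial, bound)
        return self._step_scan(
            lambda s: self.encoder.stabilised_by(traj, dict(target), s), bound)

    def activation_step(self, gene: str, schedule: PerturbationSchedule,
                        initial: Mapping[str, bool],
                        bound: int = 20) -> Dict[str, object]:
        """Earliest step of *permanent* activation of one gene: High from
        that step through the bound (and the probe step beyond it)."""
        if schedule.clamp_value(gene, bound) is False:
            raise ValueError(f"{gene} is clamped Low; activation query is vacuous")
        if self.models is not None:
            steps = [permanent_activation_step(
                self._states(i, schedule, initial, bound), gene, bound)
                for i in range(len(self.models))]
            reached = [s for s in steps if s is not None]
            out = {"step_some": min(reached) if reached else None,
                   "step_all": (max(steps) if all(s is not None
                                                  for s in steps) else None),
                   "bound": bound}
        else:
            traj = self.trajectory(schedule, initial, bound)
            enc = self.encoder
            out = self._step_scan(
                lambda s: enc._and([traj.state[(gene, t)]
                                    for t in range(s, bound + 2)]), bound)
        out["gene"] = gene
        return out

    def _step_scan(self, hyp_at, bound: int) -> Dict[str, object]:
        step_some = step_all = None
        for s in range(bound + 1):
            h = hyp_at(s)
            if step_some is None:
                if not self._solve([h]):
                    continue
                step_some = s
            if not self._solve([-h]):
                step_all = s
                break
        return {"step_some": step_some, "step_all": step_all, "bound": bound}

    # -- hypothesis queries ---------------------------------------------------
    def reach_and_hold(self, schedule: PerturbationSchedule,
                       initial: Mapping[str, bool],
                       target: Mapping[str, bool],
                       bound: int = 20) -> str:
        """Trichotomy outcome for 'the trajectory stabilises in the target'."""
        if self.models is not None:
            return self._decide_bools([
                stabilisation_step(self._states(i, schedule, initial, bound),
                                   dict(target), bound) is not None
                for i in range(len(self.models))])
        traj = self.trajectory(schedule, initial, bound)
        return self._decide_lit(self.encoder.stable_in(traj, dict(target)))

    # -- ordering queries ----------------------------------------------------
    def compare_schedules(self, schedule_a: PerturbationSchedule,
                          schedule_b: PerturbationSchedule,
                          initial: Mapping[str, bool],
                          target: Mapping[str, bool],
                          bound: int = 20,
                          mode: str = "first_hit") -> Dict[str, object]:
        """Paired-trajectory efficiency comparison with shared model
        choices.  ``a_never_slower``: in no consistent model does A reach
        the target later than B.  ``mode`` selects the step compared:
        ``first_hit`` (first step the target holds) or ``first_stable``
        (first step the trajectory has stabilised in the target)."""
        if mode not in ("first_hit", "first_stable"):
            raise ValueError(f"unknown comparison mode {mode!r}")
        tgt = dict(target)

        if self.models is not None:
            def step_of(states):
                if mode == "first_hit":
                    return first_hit_step(states, tgt, bound)
                return stabilisation_step(states, tgt, bound)

            a_never, b_never = True, True
            for i in range(len(self.models)):
                fa = step_of(self._states(i, schedule_a, initial, bound))
                fb = step_of(self._states(i, schedule_b, initial, bound))
                fa = bound + 1 if fa is None else fa
                fb = bound + 1 if fb is None else fb
                a_never &= fa <= fb
                b_never &= fb <= fa
        else:
            enc = self.encoder
            tr_a = self.trajectory(schedule_a, initial, bound)
            tr_b = self.trajectory(schedule_b, initial, bound)
            if mode == "first_hit":
                hit_a = enc.hit_by(tr_a, tgt)
                hit_b = enc.hit_by(tr_b, tgt)
            else:
                # stabilised-by-s is monotone in s, so these prefix
                # literals play the same role as the hit_by arrays
                hit_a = [enc.stabilised_by(tr_a, tgt, s)
                         for s in range(bound + 1)]
                hit_b = [enc.stabilised_by(tr_b, tgt, s)
                         for s in range(bound + 1)]
            a_slower = enc._or([enc._and([hit_b[t], -hit_a[t]])
                                for t in range(bound + 1)])
            b_slower = enc._or([enc._and([hit_a[t], -hit_b[t]])
                                for t in range(bound + 1)])
            a_never = not self._solve([a_slower])
            b_never = not self._solve([b_slower])
        if a_never and not b_never:
            outcome = "A_never_slower"
        elif b_never and not a_never:
            outcome = "B_never_slower"
        elif a_never and b_never:
            outcome = "equivalent"
        else:
            outcome = NO_PREDICTION
        return {"outcome": outcome, "a_never_slower": a_never,
                "b_never_slower": b_never}

    def precedes(self, gene_x: str, gene_y: str,
                 schedule: PerturbationSchedule,
                 initial: Mapping[str, bool],
                 bound: int = 20) -> Dict[str, object]:
        """Does activation of X always precede activation of Y?

        ``always_before`` iff no consistent model's trajectory shows Y High
        at a step at which X has not yet been High."""
        if self.models is not None:
            def violates(states, first, then):
                seen_first = False
                for t in range(bound + 1):
                    if states[t][then] and not seen_first:
                        return True
                    seen_first = seen_first or states[t][first]
                return False
            x_not_before = any(
                violates(self._states(i, schedule, initial, bound),
                         gene_x, gene_y) for i in range(len(self.models)))
            y_not_before = any(
                violates(self._states(i, schedule, initial, bound),
                         gene_y, gene_x) for i in range(len(self.models)))
        else:
            enc = self.encoder
            traj = self.trajectory(schedule, initial, bound)

            def violation(first: str, then: str) -> int:
                lits = []
                no_first = enc.TRUE
                for t in range(bound + 1):
                    lits.append(enc._and([traj.state[(then, t)], no_first]))
                    no_first = enc._and([no_first, -traj.state[(first, t)]])
                return enc._or(lits)

            x_not_before = self._solve([violation(gene_x, gene_y)])
            y_not_before = self._solve([violation(gene_y, gene_x)])
        if not x_not_before:
            outcome = "always_before"
        elif not y_not_before:
            outcome = "never_before"
        else:
            outcome = NO_PREDICTION
        return {"outcome": outcome, "x": gene_x, "y": gene_y}

    # -- perturbation queries -------------------------------------------------
    def essentiality(self, component: str, schedule: PerturbationSchedule,
                     initial: Mapping[str, bool],
                     target: Mapping[str, bool],
                     bound: int = 20) -> Dict[str, object]:
        """Clamp the component Low and ask whether the network still reaches
        and holds the target (projected onto the other components)."""
        if self.network.component(component).role == SIGNAL:
            raise ValueError("essentiality is asked of genes, not signals")
        ko = schedule.with_clamp(component, False)
        tgt = {g: v for g, v in target.items() if g != component}
        init = dict(initial)
        init[component] = False
        verdict = self.reach_and_hold(ko, init, tgt, bound)
        outcome = {POSITIVE: "dispensable", NEGATIVE: "required",
                   NO_PREDICTION: NO_PREDICTION}[verdict]
        return {"component": component, "outcome": outcome}

    def cocktail_outcome(self, cocktail: Sequence[str],
                         inputs: Mapping[str, bool],
                         target: Mapping[str, bool],
                         bound: int = 20) -> Dict[str, object]:
        """Reprogramming query: start all-off except the cocktail factors,
        clamp the cocktail High, ask for stable conversion to the target.
        Factors outside the network roster are ignored with a warning."""
        known, dropped = [], []
        for f in cocktail:
            (known if f in self.network else dropped).append(f)
        if dropped:
            logger.warning("cocktail factors outside the network ignored: %s",
                           ", ".join(dropped))
        sched = PerturbationSchedule(dict(inputs),
                                     tuple(Clamp(f, True) for f in known))
        initial = {g.name: (g.name in known) for g in self.network.genes}
        verdict = self.reach_and_hold(sched, initial, dict(target), bound)
        outcome = {POSITIVE: "reprograms", NEGATIVE: "fails",
                   NO_PREDICTION: NO_PREDICTION}[verdict]
        return {"cocktail": list(known), "ignored": dropped, "outcome": outcome}


# ---------------------------------------------------------------------------
# Declarative query batteries
# ---------------------------------------------------------------------------

def _schedule_from_dict(d: Mapping) -> PerturbationSchedule:
    clamps = tuple(Clamp(c[0], c[1] in (True, "high"),
                         c[2] if len(c) > 2 else 0,
                         c[3] if len(c) > 3 else None)
                   for c in d.get("clamps", ()))
    return PerturbationSchedule(dict(d.get("inputs", {})), clamps)


def run_battery(engine: PredictionEngine,
                battery: Sequence[Mapping]) -> List[Prediction]:
    """Evaluate a declarative list of named queries.

    Each entry is a dict with ``name``, ``type`` (reach_and_hold,
    steps_to_target, activation_step, precedes, essentiality, cocktail or
    compare_schedules) and the query's parameters (``inputs``, ``clamps``,
    ``initial``, ``target``, ``gene``/``gene_x``/``gene_y``, ``cocktail``,
    ``bound``).
    """
    out: List[Prediction] = []
    for q in battery:
        kind = q["type"]
        bound = int(q.get("bound", 20))
        sched = _schedule_from_dict(q)
        initial = dict(q.get("initial", {}))
        target = dict(q.get("target", {}))
        if kind == "reach_and_hold":
            verdict = engine.reach_and_hold(sched, initial, target, bound)
            out.append(Prediction(q["name"], verdict))
        elif kind == "steps_to_target":
            d = engine.steps_to_target(sched, initial, target, bound)
            verdict = POSITIVE if d["step_all"] is not None else (
                NO_PREDICTION if d["step_some"] is not None else NEGATIVE)
            out.append(Prediction(q["name"], verdict, d))
        elif kind == "activation_step":
            d = engine.activation_step(q["gene"], sched, initial, bound)
            verdict = POSITIVE if d["step_all"] is not None else (
                NO_PREDICTION if d["step_some"] is not None else NEGATIVE)
            out.append(Prediction(q["name"], verdict, d))
        elif kind == "precedes":
            d = engine.precedes(q["gene_x"], q["gene_y"], sched, initial,
                                bound)
            verdict = {"always_before": POSITIVE, "never_before": NEGATIVE,
                       NO_PREDICTION: NO_PREDICTION}[d["outcome"]]
            out.append(Prediction(q["name"], verdict, d))
        elif kind == "essentiality":
            d = engine.essentiality(q["gene"], sched, initial, target, bound)
            verdict = {"required": POSITIVE, "dispensable": NEGATIVE,
                       NO_PREDICTION: NO_PREDICTION}[d["outcome"]]
            out.append(Prediction(q["name"], verdict, d))
        elif kind == "cocktail":
            d = engine.cocktail_outcome(q["cocktail"], dict(q.get("inputs", {})),
                                        target, bound)
            verdict = {"reprograms": POSITIVE, "fails": NEGATIVE,
                       NO_PREDICTION: NO_PREDICTION}[d["outcome"]]
            out.append(Prediction(q["name"], verdict, d))
        elif kind == "compare_schedules":
            sched_b = _schedule_from_dict(q["schedule_b"])
            d = engine.compare_schedules(sched, sched_b, initial, target,
                                         bound)
            verdict = {"A_never_slower": POSITIVE, "B_never_slower": NEGATIVE,
                       "equivalent": POSITIVE,
                       NO_PREDICTION: NO_PREDICTION}[d["outcome"]]
            out.append(Prediction(q["name"], verdict, d))
        else:
            raise ValueError(f"unknown query type {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Scoring against experimental outcomes
# ---------------------------------------------------------------------------

@dataclass
class OutcomeRow:
    query: str
    result: str  # supports-positive | supports-negative


def score_predictions(predictions: Sequence[Prediction],
                      outcomes: Sequence[OutcomeRow]) -> Dict[str, object]:
    """Accuracy of definitive predictions against an outcome table.

    ``accuracy`` counts definitive predictions only; ``conservative_accuracy``
    counts a no-prediction as incorrect.  Outcome rows that match no
    prediction are reported, never silently dropped.
    """
    by_query = {p.query: p for p in predictions}
    n_correct = n_incorrect = n_nopred = 0
    unmapped: List[str] = []
    for row in outcomes:
        p = by_query.get(row.query)
        if p is None:
            unmapped.append(row.query)
            continue
        if p.outcome == NO_PREDICTION:
            n_nopred += 1
        elif (p.outcome == POSITIVE) == (row.result == "supports-positive"):
            n_correct += 1
        else:
            n_incorrect += 1
    tested = n_correct + n_incorrect
    return {
        "n_correct": n_correct,
        "n_incorrect": n_incorrect,
        "n_no_prediction": n_nopred,
        "n_tested": tested,
        "accuracy": (n_correct / tested) if tested else None,
        "conservative_accuracy": (n_correct / (tested + n_nopred))
                                 if tested + n_nopred else None,
        "unmapped": unmapped,
    }
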