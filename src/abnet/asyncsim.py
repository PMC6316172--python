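"""Asynchronous stochastic simulation of a single concrete model.

Under the asynchronous scheme one gene updates per step, the updating gene
chosen non-deterministically; here the choice is random.  Two policies are
provided: ``uniform`` (each step picks one unclamped gene uniformly at
random, no fairness guarantee) and ``rounds`` (random-permutation rounds, a
weakly fair schedule in which every gene updates once per round).  Signals
and clamped components keep their scheduled values throughout.

Used to cross-validate synchronous all-models predictions on one model
(e.g. the minimal model of a constrained network) by empirical reachability.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .network import (ConcreteModel, PerturbationSchedule, State,
                      apply_schedule, evaluate_condition,
                      REGULATION_CONDITIONS, SIGNAL)

UNIFORM = "uniform"
ROUNDS = "rounds"


def _update_one(model: ConcreteModel, state: State, gene: str) -> bool:
    net = model.network
    chosen = model.chosen_optional
    acts_active = acts_total = reps_active = reps_total = 0
    for edge in net.regulators_of(gene):
        if not (edge.definite or edge in chosen):
            continue
        active = state[edge.source]
        if edge.positive:
            acts_total += 1
            acts_active += active
        else:
            reps_total += 1
            reps_active += active
    cond = REGULATION_CONDITIONS[model.conditions[gene]]
    return evaluate_condition(cond, acts_active, acts_total,
                              reps_active, reps_total)


def async_trajectory(model: ConcreteModel, initial: Mapping[str, bool],
                     schedule: PerturbationSchedule = PerturbationSchedule(),
                     max_steps: int = 100, seed: int = 0,
                     policy: str = UNIFORM,
                     rng: Optional[random.Random] = None) -> List[State]:
    """One asynchronous run of ``max_steps`` single-gene updates.

    Returns max_steps+1 states.  A synchronous fixed point is absorbing
    under any update order.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if policy not in (UNIFORM, ROUNDS):
        raise ValueError(f"unknown update policy {policy!r}")
    rng = rng if rng is not None else random.Random(seed)
    net = model.network
    genes = [g.name for g in net.genes]
    states = [apply_schedule(model, initial, schedule, 0)]
    order: List[str] = []
    for t in range(max_steps):
        candidates = [g for g in genes if schedule.clamp_value(g, t + 1) is None]
        if not candidates:
            states.append(apply_schedule(model, states[-1], schedule, t + 1))
            continue
        if policy == UNIFORM:
            gene = rng.choice(candidates)
        else:
            if not order:
                order = candidates[:]
                rng.shuffle(order)
            gene = order.pop()
            while gene not in candidates and order:
                gene = order.pop()
        nxt = dict(states[-1])
        nxt[gene] = _update_one(model, states[-1], gene)
        states.append(apply_schedule(model, nxt, schedule, t + 1))
    return states


@dataclass
class AsyncRunSummary:
    n_runs: int
    max_steps: int
    seed: int
    fraction_reaching_target: float
    first_activation: Dict[str, List[int]] = field(default_factory=dict)


def _matches(state: State, partial: Mapping[str, bool]) -> bool:
    return all(state[k] == v for k, v in partial.items())


def reachability(model: ConcreteModel, initial: Mapping[str, bool],
                 schedule: PerturbationSchedule,
                 target: Mapping[str, bool],
                 max_steps: int = 100, n_runs: int = 1000, seed: int = 0,
                 policy: str = UNIFORM) -> AsyncRunSummary:
    """Empirical probability of hitting the target within ``max_steps``
    single-gene updates, plus per-gene first-activation step samples."""
    rng = random.Random(seed)
    genes = [g.name for g in model.network.genes]
    n_hit = 0
    first_act: Dict[str, List[int]] = {g: [] for g in genes}
    for _ in range(n_runs):
        states = async_trajectory(model, initial, schedule, max_steps,
                                  policy=policy, rng=rng)
        if any(_matches(s, target) for s in states):
            n_hit += 1
        for g in genes:
            for t, s in enumerate(states):
                if s[g]:
                    first_act[g].append(t)
                    break
    return AsyncRunSummary(n_runs, max_steps, seed, n_hit / n_runs, first_act)


@dataclass
class AsyncQuery:
    name: str
    kind: str                       # "reach" | "precedes"
    initial: Dict[str, bool]
    schedule: PerturbationSchedule
    target: Dict[str, bool] = field(default_factory=dict)
    gene_x: str = ""
    gene_y: str = ""
    expected: Optional[str] = None  # supports-positive / supports-negative


def async_battery(model: ConcreteModel, battery: Sequence[AsyncQuery],
                  n_runs: int = 200, max_steps: int = 100, seed: int = 0,
                  policy: str = UNIFORM,
                  reach_threshold: float = 0.0) -> Dict[str, object]:
    """Evaluate a battery of queries on one model by repeated async runs.

    Reachability queries count positive when the hit fraction exceeds the
    threshold (default: reached in at least one run); ordering queries go by
    the majority of runs in which X first activates no later than Y.
    """
    rng = random.Random(seed)
    results = []
    n_agree = n_scored = 0
    for q in battery:
        sub_seed = rng.randrange(2 ** 31)
        if q.kind == "reach":
            summ = reachability(model, q.initial, q.schedule, q.target,
                                max_steps, n_runs, sub_seed, policy)
            positive = summ.fraction_reaching_target > reach_threshold
            detail = {"fraction": summ.fraction_reaching_target}
        elif q.kind == "precedes":
            wins = 0
            for _ in range(n_runs):
                states = async_trajectory(model, q.initial, q.schedule,
                                          max_steps, policy=policy, rng=rng)
                fx = next((t for t, s in enumerate(states) if s[q.gene_x]),
                          max_steps + 1)
                fy = next((t for t, s in enumerate(states) if s[q.gene_y]),
                          max_steps + 1)
                wins += fx <= fy
            positive = wins > n_runs / 2
            detail = {"fraction_x_first": wins / n_runs}
        else:
            raise ValueError(f"unknown async query kind {q.kind!r}")
        outcome = "supports-positive" if positive else "supports-negative"
        row = {"name": q.name, "kind": q.kind, "outcome": outcome, **detail}
        if q.expected is not None:
            row["agrees"] = outcome == q.expected
            n_scored += 1
            n_agree += row["agrees"]
        results.append(row)
    return {
        "n_runs": n_runs, "max_steps": max_steps, "seed": seed,
        "policy": policy, "queries": results,
        "n_scored": n_scored,
        "agreement": (n_agree / n_scored) if n_scored else None,
    }
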