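"""Synthetic ground truth for end-to-end validation.

Generates a known concrete Boolean network (the *ground truth*), expression
datasets whose pairwise correlations reflect its interactions, and
experimental observations derived from its simulated behaviour.  Every
pipeline stage -- correlation-based inference, synthesis, classification and
prediction -- can then be validated against a known answer without external
data.

The generator emulates the shape of the study data: a handful of culture
conditions (signal on/off combinations, seven for three signals), around
twenty expression samples per condition, and log-normal expression emission
around a High and a Low mean an order of magnitude apart, mirroring the
bimodal log10 structure that 2-means discretisation assumes.

Design notes
------------
* The gene-gene wiring is acyclic, so for fixed root activities the
  synchronous dynamics settle in one unique attractor; each expression
  sample is that attractor state under per-sample stochastic signal
  transduction, plus a small per-gene state-flip noise.  Direct
  regulator-target pairs therefore correlate strongly (|r| -> 1 - 2*flip
  as the emission noise vanishes) while indirect correlations decay with
  path length, which is what makes threshold-based edge recovery sharp.
* Ground-truth regulation conditions are drawn from the activation-lenient
  subset (an active activator suffices); genes carrying repressors use the
  strict condition (any active repressor silences), keeping repressive
  edges dynamically visible.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constraints import (Expectation, ExperimentConstraint, NEVER, REACHED,
                          STABLE, partial_state)
from .inference import ExpressionDataset
from .network import (AbstractNetwork, Clamp, Component, ConcreteModel,
                      REGULATION_CONDITIONS, SIGNAL, Interaction,
                      PerturbationSchedule, evaluate_condition,
                      sync_trajectory)

#: Conditions sampled for unrepressed ground-truth genes: activation by some
#: activator suffices.  Genes with repressors use STRICT_CONDITION, under
#: which any active repressor silences the target.
_LENIENT_CONDITIONS = (2, 4, 5, 6, 7, 8)
STRICT_CONDITION = 2

#: Per-sample probability that an ON signal is transduced to its direct
#: target (cell-to-cell signalling heterogeneity).
P_TRANSDUCE = 0.8
#: Per-gene, per-sample probability of flipping the computed Boolean state.
#: Sets the correlation scale: a positive regulator-target pair correlates
#: at about 1 - 2*flip (~0.9 by default), a repressor-target pair at about
#: -0.7 in conditions where the target's activators are mostly available.
P_FLIP = 0.05
#: Basal (signal-independent) stochastic activity of signal-rooted genes;
#: keeps every lineage expressed at some level in every culture condition,
#: so no dataset's coefficients degenerate to pure noise.
P_BASAL = 0.3


@dataclass
class GroundTruth:
    model: ConcreteModel
    planted_threshold: float
    noise_sd: float
    conditions: List[Dict[str, bool]]  # signal input combinations
    seed: int
    p_flip: float = P_FLIP
    p_transduce: float = P_TRANSDUCE
    p_basal: float = P_BASAL

    @property
    def network(self) -> AbstractNetwork:
        return self.model.network

    def planted_interactions(self) -> List[Interaction]:
        """The gene-gene interactions that inference should recover."""
        return sorted(self.model.chosen_optional,
                      key=lambda i: (i.source, i.target))

    def planted_pairs(self) -> set:
        """Unordered signed gene pairs (inference calls are bidirectional)."""
        return {frozenset((i.source, i.target)) | {i.positive}
                for i in self.planted_interactions()}


def _input_combinations(signals: Sequence[str], n: int) -> List[Dict[str, bool]]:
    """Culture conditions: all signals on, then each signal withdrawn in
    turn, cycling.  Richer combinations keep most of the network expressed
    in most datasets while still isolating every signal lineage."""
    combos = [dict(zip(signals, bits))
              for bits in itertools.product([True, False], repeat=len(signals))
              if sum(bits) >= max(1, len(signals) - 1)]
    return [combos[i % len(combos)] for i in range(n)]


def sample_ground_truth(n_genes: int = 12, n_signals: int = 3,
                        n_interactions: int = 25, seed: int = 7,
                        planted_threshold: float = 0.6,
                        noise_sd: float = 0.2,
                        conditions_per_gene: int = 3,
                        structure: str = "tree") -> GroundTruth:
    """Random signed acyclic network with every gene owning an activator.

    Signal-to-gene edges are definite (signal wiring is assumed known, as
    for the culture inputs of the study); gene-gene edges are optional and
    all instantiated in the ground-truth model -- the planted interactions
    that correlation inference must recover.  Each gene's allowed condition
    set has ``conditions_per_gene`` entries including the true one, which
    bounds the candidate-model space the synthesis engine must search.

    ``structure="tree"`` (default): every gene has exactly one primary
    activator (a signal for the root genes, an earlier gene otherwise); the
    remaining interaction budget adds repressors and second activators under
    two rules that keep every planted edge dynamically visible -- a gene's
    regulators must descend from *distinct* signals (so some culture
    condition silences the co-regulators and isolates each edge), and the
    total in-degree from genes stays below the number of signals.

    ``structure="matching"``: planted gene-gene edges form disjoint pairs
    with signal-rooted sources, eliminating indirect correlation paths; use
    this to test sharp recovery (precision and recall -> 1 at low noise).
    ``n_interactions`` is ignored for this structure.
    """
    if structure not in ("tree", "matching"):
        raise ValueError(f"unknown structure {structure!r}")
    if n_interactions < n_genes:
        raise ValueError("need n_interactions >= n_genes so every gene "
                         "can have an activator")
    rng = random.Random(seed)
    genes = [f"G{i:02d}" for i in range(1, n_genes + 1)]
    signals = [f"S{i}" for i in range(1, n_signals + 1)]
    comps: List[Component] = [Component(s, SIGNAL) for s in signals]

    edges: List[Interaction] = []
    pair_taken = set()  # (src, tgt) irrespective of sign
    order = {g: i for i, g in enumerate(genes)}  # acyclic gene wiring

    def add(src: str, tgt: str, positive: bool) -> bool:
        if src == tgt or (src, tgt) in pair_taken or (tgt, src) in pair_taken:
            return False
        if src in order and order[src] >= order[tgt]:
            return False
        pair_taken.add((src, tgt))
        edges.append(Interaction(src, tgt, positive, definite=src in signals))
        return True

    if structure == "matching":
        for k in range(0, n_genes - 1, 2):
            a, b = genes[k], genes[k + 1]
            sig = signals[(k // 2) % n_signals]
            add(sig, a, True)
            if rng.random() < 0.75:
                add(a, b, True)           # b's sole activator is a
            else:
                add(signals[(k // 2 + 1) % n_signals], b, True)
                add(a, b, False)          # repression, activator from a signal
        if n_genes % 2:
            add(signals[0], genes[-1], True)
    else:
        # one primary activator per gene: roots on distinct signals, the
        # rest chaining off an earlier gene; track each gene's signal
        # ancestry through its primary activator
        root_sig: Dict[str, str] = {}
        for i, g in enumerate(genes):
            if i < n_signals:
                add(signals[i], g, True)
                root_sig[g] = signals[i]
            else:
                while True:
                    src = rng.choice(genes[:i])
                    if add(src, g, True):
                        root_sig[g] = root_sig[src]
                        break
        parents: Dict[str, List[str]] = {g: [] for g in genes}
        has_child = set()
        for e in edges:
            if e.source in order:
                parents[e.target].append(e.source)
                has_child.add(e.source)
        # extra budget: repressors (about a quarter of it) and second
        # activators, each from a different signal lineage than the target's
        # existing regulators so some culture condition isolates every edge.
        # Extras target chain-terminal genes first: gating a mid-chain gene
        # would starve everything downstream of it of expression variance.
        def try_extra(positive: bool) -> bool:
            leaves = [g for g in genes[1:] if g not in has_child]
            pool_t = leaves if leaves else genes[1:]
            tgt = rng.choice(pool_t)
            # total in-degree capped at two: a third regulator would push
            # the target's best pairwise correlation under 1/sqrt(3), below
            # any usable calling threshold
            n_sig_parents = sum(1 for e in edges
                                if e.target == tgt and e.source in signals)
            if len(parents[tgt]) + n_sig_parents >= 2:
                return False
            sigs_used = {root_sig[p] for p in parents[tgt]} | {root_sig[tgt]}
            pool = [s for s in genes[:order[tgt]]
                    if root_sig[s] not in sigs_used]
            if not pool:
                return False
            src = rng.choice(pool)
            if add(src, tgt, positive):
                parents[tgt].append(src)
                has_child.add(src)
                return True
            return False

        attempts = 0
        n_neg_budget = max(1, (n_interactions - len(edges)) // 4)
        while len(edges) < n_interactions and attempts < 2000:
            attempts += 1
            want_negative = sum(not e.positive for e in edges) < n_neg_budget
            try_extra(positive=not want_negative)

    repressed = {e.target for e in edges if not e.positive}
    n_act = {g: sum(1 for e in edges if e.target == g and e.positive)
             for g in genes}
    # multi-activator genes require all activators (AND-gating: at the high
    # activity levels the generator produces, AND preserves pairwise
    # correlation where OR would dilute it); repressed genes silence on any
    # active repressor
    def pick_cond(g: str) -> int:
        if n_act[g] >= 2:
            return 0 if g in repressed else 3
        if g in repressed:
            return STRICT_CONDITION
        return rng.choice(_LENIENT_CONDITIONS)
    true_cond = {g: pick_cond(g) for g in genes}
    allowed: Dict[str, frozenset] = {}
    for g in genes:
        pool = [c for c in range(9) if c != true_cond[g]]
        extra = rng.sample(pool, max(0, min(conditions_per_gene - 1, len(pool))))
        allowed[g] = frozenset([true_cond[g]] + extra)
    comps += [Component(g, allowed_conditions=allowed[g]) for g in genes]

    net = AbstractNetwork(comps, edges)
    model = ConcreteModel(net, frozenset(net.optional_interactions), true_cond)
    combos = _input_combinations(signals, 7)
    return GroundTruth(model, planted_threshold, noise_sd, combos, seed)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

#: log10 means of the High / Low expression modes (ratio 10).
LOG10_HIGH, LOG10_LOW = 2.0, 1.0


def _sample_state(gt: GroundTruth, inputs: Mapping[str, bool],
                  rng: np.random.Generator) -> Dict[str, bool]:
    """One attractor state draw under stochastic signal transduction."""
    net = gt.network
    genes = [g.name for g in net.genes]  # construction order is topological
    signal_names = {s.name for s in net.signals}
    state: Dict[str, bool] = {s: bool(inputs.get(s, False))
                              for s in signal_names}
    for g in genes:
        aa = at = ra = rt = 0
        for e in net.regulators_of(g):
            src_on = state[e.source]
            if e.source in signal_names:
                src_on = (src_on and rng.random() < gt.p_transduce) \
                    or rng.random() < gt.p_basal
            if e.positive:
                at += 1
                aa += src_on
            else:
                rt += 1
                ra += src_on
        cond = REGULATION_CONDITIONS[gt.model.conditions[g]]
        val = evaluate_condition(cond, aa, at, ra, rt)
        if rng.random() < gt.p_flip:
            val = not val
        state[g] = val
    return state


def simulate_expression(gt: GroundTruth, n_datasets: int = 7,
                        samples_per_dataset: int = 20,
                        seed: int = 3) -> List[ExpressionDataset]:
    """Condition-specific expression datasets.

    Each dataset fixes one signal combination and draws attractor states
    under per-sample transduction/flip noise; Boolean states map to
    continuous expression through log-normal emission (log10 sd =
    ``gt.noise_sd``), High and Low means one order of magnitude apart.
    """
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    rng = np.random.default_rng(seed)
    genes = [g.name for g in gt.network.genes]
    combos = _input_combinations([s.name for s in gt.network.signals],
                                 n_datasets)
    out = []
    for d, inputs in enumerate(combos):
        draws = [_sample_state(gt, inputs, rng)
                 for _ in range(samples_per_dataset)]
        cols = np.array([[st[g] for g in genes] for st in draws],
                        dtype=bool).T
        log_mu = np.where(cols, LOG10_HIGH, LOG10_LOW)
        expr = 10 ** (log_mu + rng.normal(0.0, gt.noise_sd, size=log_mu.shape))
        df = pd.DataFrame(expr, index=genes,
                          columns=[f"s{j}" for j in range(cols.shape[1])])
        label = "+".join(k for k, v in sorted(inputs.items()) if v) or "none"
        out.append(ExpressionDataset(df, condition_label=label,
                                     source_label=f"synthetic_d{d}"))
    return out


# ---------------------------------------------------------------------------
# Small random synthesis instances (for exhaustive cross-checking)
# ---------------------------------------------------------------------------

def sample_synthesis_instance(rng: random.Random, max_components: int = 4,
                              max_optional: int = 6, max_constraints: int = 2,
                              max_conditions: int = 3):
    """A random (network, constraints) pair small enough to enumerate all
    concrete models exhaustively; the distribution mixes modalities, clamps
    and satisfiable/unsatisfiable cases."""
    from .constraints import (Expectation, NEVER, REACHED, STABLE, SUSTAINED,
                              experiment)
    n = rng.randint(2, max_components)
    names = [f"G{i}" for i in range(n)]
    comps = [Component(nm, allowed_conditions=frozenset(
        rng.sample(range(9), rng.randint(1, max_conditions))))
        for nm in names]
    edges, seen = [], set()
    n_opt = 0
    for _ in range(rng.randint(1, max_optional + 2)):
        s, t = rng.choice(names), rng.choice(names)
        pos = rng.random() < 0.7
        definite = rng.random() < 0.25
        if (s, t, pos) in seen:
            continue
        if not definite and n_opt >= max_optional:
            definite = True
        seen.add((s, t, pos))
        n_opt += not definite
        edges.append(Interaction(s, t, pos, definite))
    net = AbstractNetwork(comps, edges)
    cons = []
    for ci in range(rng.randint(1, max_constraints)):
        initial = {nm: rng.random() < 0.5 for nm in names}
        clamps = [Clamp(rng.choice(names), rng.random() < 0.5)] \
            if rng.random() < 0.3 else []
        part = {nm: rng.random() < 0.5
                for nm in rng.sample(names, rng.randint(1, n))}
        modality = rng.choice([REACHED, NEVER, STABLE, SUSTAINED])
        cons.append(experiment(f"e{ci}", {}, initial,
                               [Expectation(modality, partial_state(part))],
                               clamps=clamps, bound=rng.randint(3, 6)))
    return net, cons


# ---------------------------------------------------------------------------
# Observation generation
# ---------------------------------------------------------------------------

@dataclass
class HeldOutQuery:
    """A prediction query whose ground-truth answer is known by simulation."""
    name: str
    schedule: PerturbationSchedule
    initial: Dict[str, bool]
    target: Dict[str, bool]
    observed: bool  # does the ground truth stably reach the target?


def _stably_reaches(model: ConcreteModel, schedule: PerturbationSchedule,
                    initial: Mapping[str, bool], target: Mapping[str, bool],
                    bound: int) -> bool:
    states, fixed = sync_trajectory(model, initial, schedule, bound)
    return fixed and all(states[bound][k] == v for k, v in target.items())


def generate_observations(gt: GroundTruth, n_experiments: int = 4,
                          n_heldout: int = 6, seed: int = 0,
                          bound: int = 20
                          ) -> Tuple[List[ExperimentConstraint],
                                     List[HeldOutQuery]]:
    """Constraints describing the ground truth's simulated behaviour, plus
    held-out queries for accuracy-recovery tests.

    Emitted constraints are satisfied by the ground-truth model by
    construction (reach / stability / never-reached behaviour read off its
    own trajectories, under resetting-, knockdown- and forced-expression-
    shaped designs).
    """
    rng = random.Random(seed)
    genes = [g.name for g in gt.network.genes]
    constraints: List[ExperimentConstraint] = []

    def random_design(idx: int) -> Tuple[PerturbationSchedule, Dict[str, bool], str]:
        inputs = gt.conditions[idx % len(gt.conditions)]
        high = rng.sample(genes, max(1, len(genes) // 4))
        initial = {g: g in high for g in genes}
        kind = ("reset", "knockdown", "forced")[idx % 3]
        clamps: Tuple[Clamp, ...] = ()
        if kind == "knockdown":
            clamps = (Clamp(rng.choice(genes), False),)
        elif kind == "forced":
            clamps = (Clamp(rng.choice(genes), True),)
        return PerturbationSchedule(dict(inputs), clamps), initial, kind

    for i in range(n_experiments):
        sched, initial, kind = random_design(i)
        states, fixed = sync_trajectory(gt.model, initial, sched, bound)
        final = {g: states[bound][g] for g in genes}
        exps = []
        if fixed:
            exps.append(Expectation(STABLE, partial_state(final)))
        else:
            exps.append(Expectation(REACHED, partial_state(final)))
        # a pattern the trajectory provably avoids, as a never-reached probe
        flip = dict(final)
        probe_gene = rng.choice(genes)
        flip[probe_gene] = not flip[probe_gene]
        if not any(all(st[k] == v for k, v in flip.items()) for st in states):
            exps.append(Expectation(NEVER, partial_state(flip)))
        constraints.append(ExperimentConstraint(
            f"obs{i}_{kind}", sched, partial_state(initial),
            tuple(exps), bound))

    heldout: List[HeldOutQuery] = []
    for j in range(n_heldout):
        sched, initial, kind = random_design(n_experiments + j)
        states, fixed = sync_trajectory(gt.model, initial, sched, bound)
        target = {g: states[bound][g]
                  for g in rng.sample(genes, max(2, len(genes) // 3))}
        if j % 2:  # half the queries probe a perturbed (usually absent) state
            flip_gene = rng.choice(sorted(target))
            target[flip_gene] = not target[flip_gene]
        observed = _stably_reaches(gt.model, sched, initial, target, bound)
        heldout.append(HeldOutQuery(f"held{j}_{kind}", sched, initial,
                                    target, observed))
    return constraints, heldout
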