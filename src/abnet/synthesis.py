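"""Constraint-based synthesis of concrete Boolean network models.

Decides whether an abstract Boolean network admits concrete models satisfying
a set of experiment constraints, enumerates and counts the consistent model
set, classifies optional interactions as required / disallowed / possible and
regulation conditions as used / unused, finds a cardinality-minimal model,
and runs component-deletion and random-network controls.

Every satisfiability verdict of "satisfiable" is backed by a witness model
that is re-simulated through :mod:`abnet.constraints` (solver-independent);
a discrepancy raises instead of silently propagating.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .constraints import (ComparativeConstraint, Constraint, Expectation,
                          ExperimentConstraint, check_constraint,
                          encode_constraints, partial_state)
from .encoding import SynthesisEncoder
from .network import (AbstractNetwork, Component, ConcreteModel, Interaction,
                      GENE, SIGNAL)

SATISFIABLE = "satisfiable"
UNSATISFIABLE = "unsatisfiable"
INDETERMINATE = "indeterminate"

#: Default per-query solver time budget, seconds.
DEFAULT_TIMEOUT = 300.0


class WitnessError(RuntimeError):
    """A solver witness failed independent re-simulation."""


@dataclass
class SynthesisResult:
    status: str
    witness: Optional[ConcreteModel] = None
    encoder: Optional[SynthesisEncoder] = None
    constraints: Tuple[Constraint, ...] = ()

    @property
    def satisfiable(self) -> bool:
        return self.status == SATISFIABLE


def _build_encoder(network: AbstractNetwork,
                   constraints: Sequence[Constraint]) -> SynthesisEncoder:
    enc = SynthesisEncoder(network)
    encode_constraints(enc, constraints)
    return enc


def _verify_witness(model: ConcreteModel,
                    constraints: Sequence[Constraint]) -> None:
    for con in constraints:
        if not check_constraint(model, con):
            raise WitnessError(
                f"witness fails constraint {getattr(con, 'name', con)!r}: "
                "encoder and simulator disagree")


def synthesize(network: AbstractNetwork, constraints: Sequence[Constraint],
               timeout: float = DEFAULT_TIMEOUT) -> SynthesisResult:
    """Decide satisfiability; on success return an independently verified
    witness model.  A solver timeout yields ``indeterminate``, never
    ``unsatisfiable``."""
    enc = _build_encoder(network, constraints)
    res = enc.solver.solve(time_budget=timeout)
    if res is None:
        return SynthesisResult(INDETERMINATE, encoder=enc,
                               constraints=tuple(constraints))
    if not res:
        return SynthesisResult(UNSATISFIABLE, encoder=enc,
                               constraints=tuple(constraints))
    model = enc.extract_model()
    _verify_witness(model, constraints)
    return SynthesisResult(SATISFIABLE, model, enc, tuple(constraints))


@dataclass
class InteractionClassification:
    required: List[Interaction] = field(default_factory=list)
    disallowed: List[Interaction] = field(default_factory=list)
    possible: List[Interaction] = field(default_factory=list)
    undetermined: List[Interaction] = field(default_factory=list)


def classify_interactions(network: AbstractNetwork,
                          constraints: Sequence[Constraint],
                          timeout: float = DEFAULT_TIMEOUT,
                          result: Optional[SynthesisResult] = None,
                          on_timeout: str = "raise"
                          ) -> InteractionClassification:
    """Required: removing the optional interaction makes the constraints
    unsatisfiable.  Disallowed: imposing it does.  Everything else stays
    possible.  Starts from a single consistent seed model; the outcome does
    not depend on which seed the solver happens to find.

    ``on_timeout="undetermined"`` records interactions whose per-query
    budget ran out instead of raising; they are never silently classified.
    """
    if on_timeout not in ("raise", "undetermined"):
        raise ValueError(f"bad on_timeout {on_timeout!r}")
    if result is None:
        result = synthesize(network, constraints, timeout)
    if not result.satisfiable:
        raise ValueError("cannot classify: constraints unsatisfiable "
                         f"(status {result.status})")
    enc = result.encoder
    witness = result.witness
    out = InteractionClassification()
    for e in network.optional_interactions:
        var = enc.edge_var[e]
        present = e in witness.chosen_optional
        sub = enc.solver.solve(assumptions=[-var if present else var],
                               time_budget=timeout)
        if sub is None:
            if on_timeout == "raise":
                raise TimeoutError(f"solver timeout classifying {e}")
            out.undetermined.append(e)
        elif sub:
            out.possible.append(e)
        else:
            (out.required if present else out.disallowed).append(e)
    return out


def classify_conditions(network: AbstractNetwork,
                        constraints: Sequence[Constraint],
                        timeout: float = DEFAULT_TIMEOUT,
                        result: Optional[SynthesisResult] = None
                        ) -> Dict[str, Dict[int, str]]:
    """Per gene, per allowed regulation condition: ``used`` iff some
    consistent model assigns it, else ``unused``."""
    if result is None:
        result = synthesize(network, constraints, timeout)
    if not result.satisfiable:
        raise ValueError("cannot classify: constraints unsatisfiable")
    enc = result.encoder
    usage: Dict[str, Dict[int, str]] = {}
    for gene in network.genes:
        usage[gene.name] = {}
        for c in sorted(gene.allowed_conditions):
            var = enc.cond_var[(gene.name, c)]
            if var == enc.TRUE:
                usage[gene.name][c] = "used"
                continue
            sub = enc.solver.solve(assumptions=[var], time_budget=timeout)
            if sub is None:
                raise TimeoutError(f"solver timeout on {gene.name} condition {c}")
            usage[gene.name][c] = "used" if sub else "unused"
    return usage


@dataclass
class ModelCount:
    count: int
    cap_exceeded: bool
    models: List[ConcreteModel] = field(default_factory=list)


def count_models(network: AbstractNetwork, constraints: Sequence[Constraint],
                 cap: int = 100000, timeout: float = DEFAULT_TIMEOUT,
                 keep_models: bool = False) -> ModelCount:
    """Exact count of consistent concrete models by iterative enumeration
    with blocking clauses over the full (topology, condition) choice vector."""
    enc = _build_encoder(network, constraints)
    n = 0
    models: List[ConcreteModel] = []
    while n < cap:
        res = enc.solver.solve(time_budget=timeout)
        if res is None:
            raise TimeoutError("solver timeout while counting models")
        if not res:
            return ModelCount(n, False, models)
        model = enc.extract_model()
        _verify_witness(model, constraints)
        if keep_models:
            models.append(model)
        blocking = [-l for l in enc.choice_literals()]
        n += 1
        if not blocking:  # no choice freedom at all: exactly one model
            return ModelCount(n, False, models)
        enc.solver.add_clause(blocking)
    return ModelCount(n, True, models)


def minimal_model(network: AbstractNetwork, constraints: Sequence[Constraint],
                  timeout: float = DEFAULT_TIMEOUT) -> ConcreteModel:
    """A consistent model with the fewest instantiated interactions
    (definite + chosen optional), certified minimal by unsatisfiability one
    below its cardinality."""
    enc = _build_encoder(network, constraints)
    res = enc.solver.solve(time_budget=timeout)
    if res is None:
        raise TimeoutError("solver timeout")
    if not res:
        raise ValueError("constraints unsatisfiable")
    best = enc.extract_model()
    k = len(best.chosen_optional)
    while k > 0:
        lit = enc.at_most_edges_lit(k - 1)
        res = enc.solver.solve(assumptions=[lit], time_budget=timeout)
        if res is None:
            raise TimeoutError("solver timeout during minimisation")
        if not res:
            break
        best = enc.extract_model()
        k = len(best.chosen_optional)
    _verify_witness(best, constraints)
    return best


# ---------------------------------------------------------------------------
# Controls
# ---------------------------------------------------------------------------

def _project_partial(pairs: Tuple[Tuple[str, bool], ...],
                     removed: str) -> Tuple[Tuple[str, bool], ...]:
    return tuple((k, v) for k, v in pairs if k != removed)


def _project_experiment(con: ExperimentConstraint,
                        removed: str) -> Optional[ExperimentConstraint]:
    if any(cl.component == removed for cl in con.schedule.clamps):
        return None  # the experiment is about the removed component
    exps = []
    for e in con.expectations:
        st = _project_partial(e.state, removed)
        if not st:
            continue
        exps.append(replace(e, state=st))
    return replace(con, initial=_project_partial(con.initial, removed),
                   expectations=tuple(exps))


def component_deletion_scan(network: AbstractNetwork,
                            constraints: Sequence[Constraint],
                            timeout: float = DEFAULT_TIMEOUT
                            ) -> Dict[str, str]:
    """Satisfiability after removing each gene (with its interactions, and
    with constraints about it dropped or projected)."""
    out: Dict[str, str] = {}
    for gene in network.genes:
        sub_net = network.without_component(gene.name)
        sub_cons: List[Constraint] = []
        for con in constraints:
            if isinstance(con, ComparativeConstraint):
                tr = _project_experiment(con.treated, gene.name)
                ref = _project_experiment(con.reference, gene.name)
                tgt = _project_partial(con.target, gene.name)
                if tr is None or ref is None or not tgt:
                    continue
                sub_cons.append(ComparativeConstraint(con.name, tr, ref, tgt))
            else:
                proj = _project_experiment(con, gene.name)
                if proj is not None:
                    sub_cons.append(proj)
        out[gene.name] = synthesize(sub_net, sub_cons, timeout).status
    return out


def random_abn_control(template: AbstractNetwork,
                       constraints: Sequence[Constraint],
                       n_models: int, seed: int,
                       timeout: float = DEFAULT_TIMEOUT) -> Dict[str, int]:
    """Random ABNs preserving the component roster and the counts of
    definite/optional and positive/negative interactions; reports how many
    are satisfiable.  Self-loops are excluded unless the template has one."""
    rng = random.Random(seed)
    comps = template.components
    genes = [c.name for c in comps if c.role == GENE]
    sources = [c.name for c in comps]
    allow_self = any(i.source == i.target for i in template.interactions)
    buckets = {(d, p): sum(1 for i in template.interactions
                           if i.definite == d and i.positive == p)
               for d in (True, False) for p in (True, False)}
    n_sat = 0
    n_indet = 0
    for _ in range(n_models):
        taken = set()
        edges = []
        for (definite, positive), count in sorted(buckets.items()):
            for _ in range(count):
                while True:
                    src = rng.choice(sources)
                    tgt = rng.choice(genes)
                    if src == tgt and not allow_self:
                        continue
                    if (src, tgt, positive) in taken:
                        continue
                    taken.add((src, tgt, positive))
                    edges.append(Interaction(src, tgt, positive, definite))
                    break
        net = AbstractNetwork(comps, edges)
        status = synthesize(net, constraints, timeout).status
        if status == SATISFIABLE:
            n_sat += 1
        elif status == INDETERMINATE:
            n_indet += 1
    return {"n_models": n_models, "n_satisfiable": n_sat,
            "n_indeterminate": n_indet, "seed": seed}
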