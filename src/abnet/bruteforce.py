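"""Exhaustive enumeration over concrete models.

Ground-truth oracle for small networks: iterates every topology (subset of
optional interactions) crossed with every regulation-condition assignment,
checking constraints by direct simulation.  Exponential in the number of
optional interactions and genes; intended for networks with a handful of
components, where it provides an independent cross-check of the SAT-based
synthesis engine.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

from .constraints import Constraint, check_constraint
from .network import AbstractNetwork, ConcreteModel, Interaction


def enumerate_concrete_models(network: AbstractNetwork) -> Iterator[ConcreteModel]:
    opts = network.optional_interactions
    genes = network.genes
    cond_choices = [sorted(g.allowed_conditions) for g in genes]
    names = [g.name for g in genes]
    for r in range(len(opts) + 1):
        for subset in itertools.combinations(opts, r):
            chosen = frozenset(subset)
            for conds in itertools.product(*cond_choices):
                yield ConcreteModel(network, chosen, dict(zip(names, conds)))


def consistent_models(network: AbstractNetwork,
                      constraints: Sequence[Constraint],
                      cap: Optional[int] = None) -> List[ConcreteModel]:
    out = []
    for model in enumerate_concrete_models(network):
        if all(check_constraint(model, con) for con in constraints):
            out.append(model)
            if cap is not None and len(out) >= cap:
                break
    return out


def brute_satisfiable(network: AbstractNetwork,
                      constraints: Sequence[Constraint]) -> bool:
    return bool(consistent_models(network, constraints, cap=1))


def brute_count(network: AbstractNetwork,
                constraints: Sequence[Constraint]) -> int:
    return len(consistent_models(network, constraints))


def brute_classify(network: AbstractNetwork,
                   constraints: Sequence[Constraint]
                   ) -> Tuple[Set[Interaction], Set[Interaction], Set[Interaction]]:
    """(required, disallowed, possible) optional interactions, from the full
    consistent-model set."""
    models = consistent_models(network, constraints)
    if not models:
        raise ValueError("constraints unsatisfiable")
    opts = set(network.optional_interactions)
    required = set(opts)
    disallowed = set(opts)
    for m in models:
        required &= m.chosen_optional
        disallowed -= m.chosen_optional
    return required, disallowed, opts - required - disallowed


def brute_conditions_used(network: AbstractNetwork,
                          constraints: Sequence[Constraint]
                          ) -> Dict[str, Dict[int, str]]:
    models = consistent_models(network, constraints)
    if not models:
        raise ValueError("constraints unsatisfiable")
    out: Dict[str, Dict[int, str]] = {}
    for g in network.genes:
        seen = {m.conditions[g.name] for m in models}
        out[g.name] = {c: ("used" if c in seen else "unused")
                       for c in sorted(g.allowed_conditions)}
    return out
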