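"""Boolean network domain model.

Components, signed definite/optional interactions, regulation conditions and
deterministic synchronous dynamics.

An *abstract* Boolean network (ABN) carries two kinds of uncertainty: optional
interactions (each concrete network either instantiates an optional edge or
not) and, per component, a choice among *regulation conditions* -- monotone
Boolean update rules expressed over how many of the component's activators and
repressors are currently active (none / some / all).  A concrete model fixes
both choices, after which the synchronous dynamics are fully deterministic.

Signals (culture inputs such as LIF, CH, PD) are clamp-only components: they
have no regulators and hold whatever value the experimental condition assigns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

# Availability levels for a regulator class.
NONE, SOME, ALL = 0, 1, 2
_LEVELS = (NONE, SOME, ALL)

State = Dict[str, bool]


# ---------------------------------------------------------------------------
# Regulation conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulationCondition:
    """A monotone Boolean update rule on the (activator, repressor) level grid.

    ``table[(a, r)]`` gives the target's next value when the availability of
    its instantiated activators is at level ``a`` and of its repressors at
    level ``r``.  Every condition requires at least one active activator:
    the ``a == NONE`` row is identically False.
    """

    index: int
    table: Mapping[Tuple[int, int], bool]

    def output(self, act_level: int, rep_level: int) -> bool:
        return self.table[(act_level, rep_level)]

    def n_true(self) -> int:
        return sum(self.table.values())


def _table_key(table: Mapping[Tuple[int, int], bool]) -> tuple:
    cells = tuple(table[(a, r)] for a in _LEVELS for r in _LEVELS)
    return (sum(cells), cells)


def enumerate_regulation_conditions() -> List[RegulationCondition]:
    """Enumerate the canonical regulation conditions 0..8.

    These are exactly the Boolean maps on the 3x3 level grid that are
    (i) False whenever the activator level is ``none``,
    (ii) monotone non-decreasing in activator level and non-increasing in
    repressor level, and (iii) True at (``all``, ``none``).
    There are precisely nine, ordered here from least permissive (fewest True
    cells) to most permissive, ties broken lexicographically on the table read
    activator-major / repressor-minor.
    """
    free_cells = [(a, r) for a in (SOME, ALL) for r in _LEVELS]
    found = []
    for bits in itertools.product((False, True), repeat=len(free_cells)):
        table = {(NONE, r): False for r in _LEVELS}
        table.update(dict(zip(free_cells, bits)))
        if not table[(ALL, NONE)]:
            continue
        monotone = all(
            (table[(a, r)] <= table[(a2, r)] if a <= a2 else True)
            and (table[(a, r)] >= table[(a, r2)] if r <= r2 else True)
            for a in _LEVELS for r in _LEVELS
            for a2 in _LEVELS for r2 in _LEVELS
        )
        if monotone:
            found.append(table)
    found.sort(key=_table_key)
    return [RegulationCondition(i, t) for i, t in enumerate(found)]


#: The canonical conditions, computed once at import.
REGULATION_CONDITIONS: List[RegulationCondition] = enumerate_regulation_conditions()
N_CONDITIONS = len(REGULATION_CONDITIONS)


def _level(n_active: int, n_total: int) -> int:
    if n_active < 0 or n_total < 0 or n_active > n_total:
        raise ValueError("invalid regulator counts")
    if n_active == 0:
        return NONE
    if n_active == n_total:
        return ALL
    return SOME


def evaluate_condition(cond: RegulationCondition,
                       n_active_activators: int, n_activators: int,
                       n_active_repressors: int, n_repressors: int) -> bool:
    """Evaluate a regulation condition on regulator counts.

    A component with no instantiated activators is never expressed; a
    component with no instantiated repressors has repressor level ``none``.
    """
    if n_activators == 0:
        return False
    return cond.output(_level(n_active_activators, n_activators),
                       _level(n_active_repressors, n_repressors))


# ---------------------------------------------------------------------------
# Network structure
# ---------------------------------------------------------------------------

GENE = "gene"
SIGNAL = "signal"


@dataclass(frozen=True)
class Component:
    name: str
    role: str = GENE
    allowed_conditions: FrozenSet[int] = frozenset(range(N_CONDITIONS))

    def __post_init__(self):
        if self.role not in (GENE, SIGNAL):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == GENE and not self.allowed_conditions:
            raise ValueError(f"gene {self.name} has no allowed regulation conditions")
        if not all(0 <= c < N_CONDITIONS for c in self.allowed_conditions):
            raise ValueError("regulation condition index out of range 0..8")


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    positive: bool
    definite: bool

    @property
    def sign(self) -> str:
        return "positive" if self.positive else "negative"

    def __str__(self):
        arrow = "->" if self.positive else "-|"
        kind = "definite" if self.definite else "optional"
        return f"{self.source} {arrow} {self.target} ({kind})"


class AbstractNetwork:
    """Components plus definite/optional signed interactions.

    With *n* optional interactions the network implicitly defines 2^n
    candidate topologies (before regulation-condition choices).
    """

    def __init__(self, components: Iterable[Component],
                 interactions: Iterable[Interaction]):
        self.components: List[Component] = list(components)
        self.interactions: List[Interaction] = list(interactions)
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")
        self._by_name = {c.name: c for c in self.components}
        seen = set()
        for it in self.interactions:
            if it.source not in self._by_name:
                raise ValueError(f"unknown source component {it.source!r}")
            if it.target not in self._by_name:
                raise ValueError(f"unknown target component {it.target!r}")
            if self._by_name[it.target].role == SIGNAL:
                raise ValueError(f"signal {it.target!r} cannot be a target")
            key = (it.source, it.target, it.positive)
            if key in seen:
                raise ValueError(f"duplicate interaction {it}")
            seen.add(key)

    # -- accessors ---------------------------------------------------------
    def component(self, name: str) -> Component:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def genes(self) -> List[Component]:
        return [c for c in self.components if c.role == GENE]

    @property
    def signals(self) -> List[Component]:
        return [c for c in self.components if c.role == SIGNAL]

    @property
    def optional_interactions(self) -> List[Interaction]:
        return [i for i in self.interactions if not i.definite]

    @property
    def definite_interactions(self) -> List[Interaction]:
        return [i for i in self.interactions if i.definite]

    def regulators_of(self, target: str) -> List[Interaction]:
        return [i for i in self.interactions if i.target == target]

    def without_component(self, name: str) -> "AbstractNetwork":
        """Copy of the network with one gene (and its edges) removed."""
        if self._by_name[name].role == SIGNAL:
            raise ValueError("cannot remove a signal component")
        comps = [c for c in self.components if c.name != name]
        edges = [i for i in self.interactions if name not in (i.source, i.target)]
        return AbstractNetwork(comps, edges)

    def __repr__(self):
        return (f"AbstractNetwork({len(self.components)} components, "
                f"{len(self.definite_interactions)} definite + "
                f"{len(self.optional_interactions)} optional interactions)")


@dataclass(frozen=True)
class ConcreteModel:
    """One instantiation of the optional interactions plus one regulation
    condition per gene."""

    network: AbstractNetwork
    chosen_optional: FrozenSet[Interaction]
    conditions: Mapping[str, int]

    def __post_init__(self):
        opts = set(self.network.optional_interactions)
        if not set(self.chosen_optional) <= opts:
            raise ValueError("chosen_optional not a subset of the optional interactions")
        for g in self.network.genes:
            c = self.conditions.get(g.name)
            if c is None or c not in g.allowed_conditions:
                raise ValueError(f"gene {g.name}: condition {c} not allowed")

    def instantiated(self) -> List[Interaction]:
        return [i for i in self.network.interactions
                if i.definite or i in self.chosen_optional]

    def n_interactions(self) -> int:
        return len(self.instantiated())


# ---------------------------------------------------------------------------
# Perturbations and dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clamp:
    component: str
    value: bool
    start: int = 0
    end: Optional[int] = None  # inclusive; None = to the end of the trajectory

    def active_at(self, step: int) -> bool:
        return step >= self.start and (self.end is None or step <= self.end)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Culture inputs (signal values) plus forced-expression / knockdown clamps.

    Forced expression is a clamp High over the whole trajectory, knockdown a
    clamp Low; finite windows model transient (DOX-style) induction.
    """

    inputs: Mapping[str, bool] = field(default_factory=dict)
    clamps: Tuple[Clamp, ...] = ()

    def clamp_value(self, component: str, step: int) -> Optional[bool]:
        for cl in self.clamps:
            if cl.component == component and cl.active_at(step):
                return cl.value
        return None

    def with_clamp(self, component: str, value: bool,
                   start: int = 0, end: Optional[int] = None) -> "PerturbationSchedule":
        return PerturbationSchedule(self.inputs,
                                    self.clamps + (Clamp(component, value, start, end),))


def _value_at(schedule: PerturbationSchedule, comp: Component, step: int,
              computed: bool) -> bool:
    clamped = schedule.clamp_value(comp.name, step)
    if clamped is not None:
        return clamped
    if comp.role == SIGNAL:
        return bool(schedule.inputs.get(comp.name, False))
    return computed


def apply_schedule(model_or_network, state: Mapping[str, bool],
                   schedule: PerturbationSchedule, step: int) -> State:
    """Overlay signal inputs and active clamps on a state at a given step."""
    net = getattr(model_or_network, "network", model_or_network)
    return {c.name: _value_at(schedule, c, step, bool(state.get(c.name, False)))
            for c in net.components}


def sync_step(model: ConcreteModel, state: Mapping[str, bool],
              schedule: PerturbationSchedule = PerturbationSchedule(),
              step: int = 0) -> State:
    """One synchronous update: every gene reads its instantiated regulators in
    ``state`` (the state at ``step``) and the result is the state at ``step+1``.
    """
    net = model.network
    for name in state:
        if name not in net:
            raise ValueError(f"state references unknown component {name!r}")
    chosen = set(model.chosen_optional)
    nxt: State = {}
    for comp in net.components:
        if comp.role == SIGNAL:
            nxt[comp.name] = _value_at(schedule, comp, step + 1, False)
            continue
        acts_active = acts_total = reps_active = reps_total = 0
        for edge in net.regulators_of(comp.name):
            if not (edge.definite or edge in chosen):
                continue
            active = bool(state[edge.source])
            if edge.positive:
                acts_total += 1
                acts_active += active
            else:
                reps_total += 1
                reps_active += active
        cond = REGULATION_CONDITIONS[model.conditions[comp.name]]
        computed = evaluate_condition(cond, acts_active, acts_total,
                                      reps_active, reps_total)
        nxt[comp.name] = _value_at(schedule, comp, step + 1, computed)
    return nxt


def sync_trajectory(model: ConcreteModel, initial: Mapping[str, bool],
                    schedule: PerturbationSchedule = PerturbationSchedule(),
                    bound: int = 20) -> Tuple[List[State], bool]:
    """Deterministic synchronous trajectory of ``bound`` update steps.

    Returns ``bound + 1`` states (step 0 .. bound) and a fixed-point flag:
    True iff one further update from the final state reproduces it.
    The initial state is completed with signal inputs and step-0 clamps;
    unspecified genes default to Low.
    """
    if bound < 1:
        raise ValueError("bound must be >= 1")
    states = [apply_schedule(model, initial, schedule, 0)]
    for t in range(bound):
        states.append(sync_step(model, states[-1], schedule, t))
    probe = sync_step(model, states[-1], schedule, bound)
    return states, probe == states[-1]
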