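"""CNF encoding of bounded Boolean-network synthesis.

The synthesis question -- does some concrete model (a choice of optional
interactions plus a regulation condition per gene) generate trajectories
satisfying every encoded experiment -- is compiled to propositional logic
and handed to the CDCL solver:

* one Boolean choice variable per optional interaction,
* a one-hot block of choice variables per gene over its allowed regulation
  conditions,
* one Boolean state variable per (experiment, component, step), with the
  synchronous transition relation unrolled to each experiment's bound plus
  one extra step so that fixed-point (stability) checks read
  ``state(bound) == state(bound+1)``.

All experiments share the choice variables, so a satisfying assignment is a
single concrete model consistent with every constraint at once.  Hypotheses
for prediction queries are encoded as reified literals and activated through
solver assumptions, which keeps one incremental solver per constrained
network.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .network import (ALL, NONE, REGULATION_CONDITIONS, SIGNAL, SOME,
                      AbstractNetwork, ConcreteModel, Interaction,
                      PerturbationSchedule)
from .sat import Solver

_LEVEL_LITS = {
    # level -> literals over (some, all) aux vars, as (polarity, which) pairs
    NONE: (("neg", "some"),),
    SOME: (("pos", "some"), ("neg", "all")),
    ALL: (("pos", "all"),),
}


class Trajectory:
    """Handle to one unrolled experiment inside an encoder."""

    def __init__(self, name: str, schedule: PerturbationSchedule, bound: int):
        self.name = name
        self.schedule = schedule
        self.bound = bound
        self.state: Dict[Tuple[str, int], int] = {}  # (component, step) -> literal


class SynthesisEncoder:
    def __init__(self, network: AbstractNetwork):
        self.network = network
        self.solver = Solver()
        self.TRUE = self.solver.new_var()
        self.solver.add_clause([self.TRUE])
        self.edge_var: Dict[Interaction, int] = {}
        for edge in network.interactions:
            self.edge_var[edge] = self.TRUE if edge.definite \
                else self.solver.new_var(hint_phase=True)
        self.cond_var: Dict[Tuple[str, int], int] = {}
        for gene in network.genes:
            allowed = sorted(gene.allowed_conditions)
            if len(allowed) == 1:
                self.cond_var[(gene.name, allowed[0])] = self.TRUE
                continue
            block = [self.solver.new_var() for _ in allowed]
            for c, v in zip(allowed, block):
                self.cond_var[(gene.name, c)] = v
            self.solver.add_clause(block)
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    self.solver.add_clause([-block[i], -block[j]])
        self.trajectories: Dict[str, Trajectory] = {}
        self._edge_order = [e for e in network.interactions if not e.definite]
        self._card_outputs: Optional[List[List[int]]] = None
        # trajectories are functions of the choices: search there first
        self.solver.set_priority(
            [v for v in self.edge_var.values() if v != self.TRUE] +
            [v for v in self.cond_var.values() if v != self.TRUE])

    # -- low-level helpers --------------------------------------------------
    def _new(self) -> int:
        return self.solver.new_var()

    def _and(self, lits: Sequence[int]) -> int:
        lits = [l for l in lits if l != self.TRUE]
        if any(l == -self.TRUE for l in lits):
            return -self.TRUE
        if not lits:
            return self.TRUE
        if len(lits) == 1:
            return lits[0]
        a = self._new()
        for l in lits:
            self.solver.add_clause([-a, l])
        self.solver.add_clause([a] + [-l for l in lits])
        return a

    def _or(self, lits: Sequence[int]) -> int:
        return -self._and([-l for l in lits])

    def _eq(self, a: int, b: int) -> int:
        """Literal for a <-> b."""
        if a == b:
            return self.TRUE
        if a == -b:
            return -self.TRUE
        for const, other in ((self.TRUE, b), (-self.TRUE, b)):
            if a == const:
                return other if const == self.TRUE else -other
        if b == self.TRUE:
            return a
        if b == -self.TRUE:
            return -a
        e = self._new()
        self.solver.add_clause([-e, -a, b])
        self.solver.add_clause([-e, a, -b])
        self.solver.add_clause([e, a, b])
        self.solver.add_clause([e, -a, -b])
        return e

    # -- trajectory unrolling ----------------------------------------------
    def add_trajectory(self, name: str, schedule: PerturbationSchedule,
                       initial: Mapping[str, bool], bound: int = 20) -> Trajectory:
        """Unroll one experiment for ``bound + 1`` synchronous steps.

        Unspecified genes in the initial state default to Low.  Signals and
        clamped components are fixed by unit clauses at every step they are
        held; the extra step ``bound + 1`` supports stability probes.
        """
        if name in self.trajectories:
            raise ValueError(f"duplicate trajectory name {name!r}")
        traj = Trajectory(name, schedule, bound)
        self.trajectories[name] = traj
        net = self.network
        n_steps = bound + 1  # transitions; states 0 .. bound+1
        for comp_name in initial:
            if comp_name not in net:
                raise ValueError(f"initial state references unknown component {comp_name!r}")

        # state variables with units for signals, clamps and the initial state
        for comp in net.components:
            for t in range(n_steps + 1):
                clamped = schedule.clamp_value(comp.name, t)
                if clamped is not None:
                    lit = self.TRUE if clamped else -self.TRUE
                elif comp.role == SIGNAL:
                    lit = self.TRUE if schedule.inputs.get(comp.name, False) else -self.TRUE
                elif t == 0:
                    lit = self.TRUE if initial.get(comp.name, False) else -self.TRUE
                else:
                    lit = self._new()
                traj.state[(comp.name, t)] = lit

        # transition relation for unclamped genes
        for comp in net.genes:
            regs = net.regulators_of(comp.name)
            activators = [e for e in regs if e.positive]
            repressors = [e for e in regs if not e.positive]
            for t in range(n_steps):
                nxt = traj.state[(comp.name, t + 1)]
                if schedule.clamp_value(comp.name, t + 1) is not None:
                    continue  # value pinned; no update clause
                levels = {}
                for cls, edges in (("act", activators), ("rep", repressors)):
                    present, notblocked = [], []
                    for e in edges:
                        src = traj.state[(e.source, t)]
                        ev = self.edge_var[e]
                        if ev == self.TRUE:
                            present.append(src)
                            notblocked.append(src)
                        else:
                            present.append(self._and([ev, src]))
                            notblocked.append(self._or([-ev, src]))
                    some = self._or(present) if present else -self.TRUE
                    allv = self._and([some] + notblocked) if present else -self.TRUE
                    levels[cls] = {"some": some, "all": allv}
                # no active activator -> Low, independent of condition
                self.solver.add_clause([levels["act"]["some"], -nxt])
                for (g, c), cv in self.cond_var.items():
                    if g != comp.name:
                        continue
                    table = REGULATION_CONDITIONS[c].table
                    for a_lev in (SOME, ALL):
                        for r_lev in (NONE, SOME, ALL):
                            out = table[(a_lev, r_lev)]
                            clause = [-cv] if cv != self.TRUE else []
                            for pol, which in _LEVEL_LITS[a_lev]:
                                lit = levels["act"][which]
                                clause.append(-lit if pol == "pos" else lit)
                            for pol, which in _LEVEL_LITS[r_lev]:
                                lit = levels["rep"][which]
                                clause.append(-lit if pol == "pos" else lit)
                            clause.append(nxt if out else -nxt)
                            self.solver.add_clause(clause)
        return traj

    # -- expectation reification -------------------------------------------
    def holds_at(self, traj: Trajectory, partial: Mapping[str, bool], t: int) -> int:
        """Literal: the partial state holds at step t."""
        lits = []
        for name, val in partial.items():
            s = traj.state[(name, t)]
            lits.append(s if val else -s)
        return self._and(lits)

    def reached_in(self, traj: Trajectory, partial: Mapping[str, bool],
                   t_from: int, t_to: int) -> int:
        return self._or([self.holds_at(traj, partial, t)
                         for t in range(t_from, t_to + 1)])

    def never_in(self, traj: Trajectory, partial: Mapping[str, bool],
                 t_from: int, t_to: int) -> int:
        return -self.reached_in(traj, partial, t_from, t_to)

    def fixed_point_at_bound(self, traj: Trajectory) -> int:
        b = traj.bound
        eqs = [self._eq(traj.state[(c.name, b)], traj.state[(c.name, b + 1)])
               for c in self.network.components]
        return self._and(eqs)

    def stable_in(self, traj: Trajectory, partial: Mapping[str, bool]) -> int:
        """Target holds at the bound and the final state is a fixed point."""
        return self._and([self.holds_at(traj, partial, traj.bound),
                          self.fixed_point_at_bound(traj)])

    def sustained_in(self, traj: Trajectory, partial: Mapping[str, bool]) -> int:
        """Target holds at two sequential final steps (partial-state variant
        of stability, used when the full final state is not pinned down)."""
        b = traj.bound
        return self._and([self.holds_at(traj, partial, b - 1),
                          self.holds_at(traj, partial, b)])

    def stabilised_by(self, traj: Trajectory, partial: Mapping[str, bool],
                      step: int) -> int:
        """Target holds from ``step`` through the bound+1 probe and the final
        state is a fixed point: the trajectory has settled in the target."""
        lits = [self.holds_at(traj, partial, t)
                for t in range(step, traj.bound + 2)]
        lits.append(self.fixed_point_at_bound(traj))
        return self._and(lits)

    def hit_by(self, traj: Trajectory, partial: Mapping[str, bool]) -> List[int]:
        """Monotone prefix literals h[t] = target held at some step <= t."""
        out = []
        prev = -self.TRUE
        for t in range(traj.bound + 1):
            prev = self._or([prev, self.holds_at(traj, partial, t)])
            out.append(prev)
        return out

    def assert_lit(self, lit: int) -> None:
        self.solver.add_clause([lit])

    # -- cardinality over optional edges ------------------------------------
    def at_most_edges_lit(self, k: int) -> int:
        """Assumption literal forcing at most ``k`` optional edges present.

        Uses a sequential-counter ladder built once; ``-R[n-1][k]`` asserts
        that no k+1 edges are instantiated.
        """
        n = len(self._edge_order)
        if k >= n:
            return self.TRUE
        if self._card_outputs is None:
            R: List[List[int]] = []
            prev: List[int] = []
            for i, e in enumerate(self._edge_order):
                ev = self.edge_var[e]
                row = [self._new() for _ in range(i + 1)]
                # row[j] = at least j+1 of the first i+1 edges
                self.solver.add_clause([-ev, row[0]])
                if prev:
                    for j in range(len(prev)):
                        self.solver.add_clause([-prev[j], row[j]])
                        self.solver.add_clause([-prev[j], -ev, row[j + 1]])
                R.append(row)
                prev = row
            self._card_outputs = R
        return -self._card_outputs[-1][k]

    # -- model extraction ----------------------------------------------------
    def extract_model(self) -> ConcreteModel:
        sol = self.solver
        chosen = frozenset(e for e in self._edge_order
                           if sol.value(self.edge_var[e]))
        conds = {}
        for (g, c), v in self.cond_var.items():
            if v == self.TRUE or sol.value(v):
                if g not in conds:
                    conds[g] = c
        return ConcreteModel(self.network, chosen, conds)

    def choice_literals(self) -> List[int]:
        """Current assignment of all choice variables (for blocking)."""
        sol = self.solver
        lits = []
        for e in self._edge_order:
            v = self.edge_var[e]
            lits.append(v if sol.value(v) else -v)
        for (g, c), v in self.cond_var.items():
            if v == self.TRUE:
                continue
            lits.append(v if sol.value(v) else -v)
        return lits
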