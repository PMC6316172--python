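"""A compact CDCL SAT solver.

Conflict-driven clause learning with two-watched-literal propagation,
first-UIP learning, activity-based branching (exponential VSIDS), phase
saving and Luby restarts.  Literals
follow the DIMACS convention: variables are positive integers, negation is
arithmetic negation.

The synthesis problems this package generates are bounded-model-checking
unrollings of deterministic Boolean dynamics: once the model-choice variables
are decided, everything else follows by unit propagation.  ``set_priority``
restricts branching to those choice variables, which keeps the search in the
small combinatorial core of the problem.

``Solver.solve`` accepts assumption literals and returns True (satisfiable),
False (unsatisfiable) or None when a conflict/time budget is exhausted.
"""

from __future__ import annotations

import time
from heapq import heappop, heappush
from typing import Iterable, List, Optional, Sequence

UNASSIGNED = -1


def _luby(x: int) -> int:
    # Luby restart sequence 1,1,2,1,1,2,4,... (0-indexed)
    size, seq = 1, 0
    while size < x + 1:
        seq += 1
        size = 2 * size + 1
    while size - 1 != x:
        size = (size - 1) // 2
        seq -= 1
        x = x % size
    return 1 << seq


def _widx(lit: int) -> int:
    # literal -> watch-list index
    return 2 * lit if lit > 0 else -2 * lit + 1


class Solver:
    def __init__(self):
        self.n_vars = 0
        self.clauses: List[List[int]] = []     # problem + learnt clauses
        self.n_problem_clauses = 0
        self.watches: List[List[int]] = [[], []]  # widx -> clause indices
        self.assigns: List[int] = [UNASSIGNED]    # var -> 0/1/UNASSIGNED
        self.level: List[int] = [0]
        self.reason: List[Optional[int]] = [None]  # var -> clause index
        self.trail: List[int] = []
        self.trail_lim: List[int] = []
        self.qhead = 0
        self.activity: List[float] = [0.0]
        self.var_inc = 1.0
        self.var_decay = 0.95
        self.phase: List[bool] = [False]
        self.order_heap: List[tuple] = []  # (-activity, var), lazy entries
        self.priority_heap: List[tuple] = []
        self.is_priority: List[int] = [0]
        self._seen = bytearray(1)
        self.ok = True
        self.stats = {"conflicts": 0, "decisions": 0, "propagations": 0}

    # -- problem construction ---------------------------------------------
    def new_var(self, hint_phase: bool = False) -> int:
        self.n_vars += 1
        self.assigns.append(UNASSIGNED)
        self.level.append(0)
        self.reason.append(None)
        self.activity.append(0.0)
        self.phase.append(hint_phase)
        self.is_priority.append(0)
        self._seen.append(0)
        self.watches.append([])
        self.watches.append([])
        heappush(self.order_heap, (0.0, self.n_vars))
        return self.n_vars

    def ensure_vars(self, n: int) -> None:
        while self.n_vars < n:
            self.new_var()

    def set_priority(self, variables: Iterable[int]) -> None:
        """Branch on these variables before any others."""
        for v in variables:
            self.ensure_vars(v)
            if not self.is_priority[v]:
                self.is_priority[v] = 1
                heappush(self.priority_heap, (-self.activity[v], v))

    def value_lit(self, lit: int) -> int:
        v = self.assigns[abs(lit)]
        if v == UNASSIGNED:
            return UNASSIGNED
        return v if lit > 0 else 1 - v

    def add_clause(self, lits: Iterable[int]) -> bool:
        """Add a clause; returns False if the formula became trivially UNSAT."""
        if not self.ok:
            return False
        if self.trail_lim:
            self._cancel_until(0)
        seen = set()
        out: List[int] = []
        for lit in lits:
            if lit == 0:
                raise ValueError("literal 0 is not allowed")
            self.ensure_vars(abs(lit))
            if -lit in seen:
                return True  # tautology
            if lit not in seen:
                seen.add(lit)
                out.append(lit)
        # top-level simplification against root-level assignments
        out2 = []
        for lit in out:
            v = self.value_lit(lit)
            if v == 1:
                return True
            if v == UNASSIGNED:
                out2.append(lit)
        out = out2
        if not out:
            self.ok = False
            return False
        if len(out) == 1:
            if not self._enqueue(out[0], None):
                self.ok = False
                return False
            self.ok = self.propagate() is None
            return self.ok
        ci = len(self.clauses)
        self.clauses.append(out)
        self.n_problem_clauses += 1
        self.watches[_widx(out[0])].append(ci)
        self.watches[_widx(out[1])].append(ci)
        return True

    # -- assignment management --------------------------------------------
    def _enqueue(self, lit: int, reason: Optional[int]) -> bool:
        v = self.value_lit(lit)
        if v == 0:
            return False
        if v == 1:
            return True
        var = abs(lit)
        self.assigns[var] = 1 if lit > 0 else 0
        self.level[var] = len(self.trail_lim)
        self.reason[var] = reason
        self.trail.append(lit)
        return True

    def propagate(self) -> Optional[int]:
        """Unit propagation; returns a conflicting clause index or None."""
        assigns = self.assigns
        clauses = self.clauses
        watches = self.watches
        trail = self.trail
        level = self.level
        reason = self.reason
        nprops = 0
        confl = None
        while self.qhead < len(trail):
            lit = trail[self.qhead]
            self.qhead += 1
            nprops += 1
            neg = -lit
            wi = _widx(neg)
            watchlist = watches[wi]
            if not watchlist:
                continue
            new_list: List[int] = []
            i, n = 0, len(watchlist)
            while i < n:
                ci = watchlist[i]
                i += 1
                clause = clauses[ci]
                if clause[0] == neg:
                    clause[0], clause[1] = clause[1], clause[0]
                first = clause[0]
                a = assigns[first] if first > 0 else assigns[-first]
                if (a == 1) if first > 0 else (a == 0):  # satisfied
                    new_list.append(ci)
                    continue
                moved = False
                for k in range(2, len(clause)):
                    q = clause[k]
                    aq = assigns[q] if q > 0 else assigns[-q]
                    if not ((aq == 0) if q > 0 else (aq == 1)):  # not false
                        clause[1], clause[k] = q, clause[1]
                        watches[_widx(q)].append(ci)
                        moved = True
                        break
                if moved:
                    continue
                new_list.append(ci)
                if a == UNASSIGNED:
                    var = abs(first)
                    assigns[var] = 1 if first > 0 else 0
                    level[var] = len(self.trail_lim)
                    reason[var] = ci
                    trail.append(first)
                else:  # conflict
                    new_list.extend(watchlist[i:])
                    watches[wi] = new_list
                    self.qhead = len(trail)
                    confl = ci
                    break
            else:
                watches[wi] = new_list
                continue
            watches[wi] = new_list
            break
        self.stats["propagations"] += nprops
        return confl

    def _bump(self, var: int) -> None:
        self.activity[var] += self.var_inc
        if self.activity[var] > 1e100:
            for v in range(1, self.n_vars + 1):
                self.activity[v] *= 1e-100
            self.var_inc *= 1e-100
            self.order_heap = [(-self.activity[v], v)
                               for v in range(1, self.n_vars + 1)
                               if self.assigns[v] == UNASSIGNED
                               and not self.is_priority[v]]
            self.order_heap.sort()
            self.priority_heap = [(-self.activity[v], v)
                                  for v in range(1, self.n_vars + 1)
                                  if self.assigns[v] == UNASSIGNED
                                  and self.is_priority[v]]
            self.priority_heap.sort()
            return
        heap = self.priority_heap if self.is_priority[var] else self.order_heap
        heappush(heap, (-self.activity[var], var))

    def _analyze(self, confl: int):
        seen = self._seen
        to_clear: List[int] = []
        learnt = [0]
        counter = 0
        lit = None
        idx = len(self.trail) - 1
        cur_level = len(self.trail_lim)
        while True:
            clause = self.clauses[confl]
            for q in (clause if lit is None else clause[1:]):
                var = abs(q)
                if not seen[var] and self.level[var] > 0:
                    seen[var] = 1
                    to_clear.append(var)
                    self._bump(var)
                    if self.level[var] >= cur_level:
                        counter += 1
                    else:
                        learnt.append(q)
            while True:
                lit = self.trail[idx]
                idx -= 1
                if seen[abs(lit)]:
                    break
            counter -= 1
            if counter == 0:
                break
            confl = self.reason[abs(lit)]
            seen[abs(lit)] = 0
        learnt[0] = -lit
        for var in to_clear:
            seen[var] = 0

        if len(learnt) == 1:
            bt = 0
        else:
            bt = max(self.level[abs(q)] for q in learnt[1:])
        return learnt, bt

    def _cancel_until(self, lvl: int) -> None:
        if len(self.trail_lim) <= lvl:
            return
        bound = self.trail_lim[lvl]
        for lit in reversed(self.trail[bound:]):
            var = abs(lit)
            self.phase[var] = self.assigns[var] == 1
            self.assigns[var] = UNASSIGNED
            self.reason[var] = None
            heap = self.priority_heap if self.is_priority[var] else self.order_heap
            heappush(heap, (-self.activity[var], var))
        del self.trail[bound:]
        del self.trail_lim[lvl:]
        self.qhead = len(self.trail)

    def _record(self, learnt: List[int]) -> None:
        if len(learnt) == 1:
            self._enqueue(learnt[0], None)
            return
        ci = len(self.clauses)
        self.clauses.append(learnt)
        self.watches[_widx(learnt[0])].append(ci)
        # second watch: a literal from the backtrack level
        bt = max(range(1, len(learnt)), key=lambda k: self.level[abs(learnt[k])])
        learnt[1], learnt[bt] = learnt[bt], learnt[1]
        self.watches[_widx(learnt[1])].append(ci)
        self._enqueue(learnt[0], ci)

    def _decide(self) -> int:
        assigns = self.assigns
        heap = self.priority_heap
        while heap:
            _, var = heappop(heap)
            if assigns[var] == UNASSIGNED:
                return var
        heap = self.order_heap
        while heap:
            _, var = heappop(heap)
            if assigns[var] == UNASSIGNED:
                return var
        # heap exhausted by stale entries: rebuild from scratch
        for v in range(1, self.n_vars + 1):
            if assigns[v] == UNASSIGNED:
                heappush(heap, (-self.activity[v], v))
        while heap:
            _, var = heappop(heap)
            if assigns[var] == UNASSIGNED:
                return var
        return 0

    # -- main search --------------------------------------------------------
    def solve(self, assumptions: Sequence[int] = (),
              conflict_budget: Optional[int] = None,
              time_budget: Optional[float] = None) -> Optional[bool]:
        if not self.ok:
            return False
        self._cancel_until(0)
        if self.propagate() is not None:
            self.ok = False
            return False
        deadline = None if time_budget is None else time.monotonic() + time_budget
        start_conflicts = self.stats["conflicts"]
        restart_i = 0
        restart_lim = 100 * _luby(0)
        conflicts_since_restart = 0

        # place assumptions as pseudo-decisions at successive levels
        def apply_assumptions() -> Optional[bool]:
            for a in assumptions:
                self.ensure_vars(abs(a))
                v = self.value_lit(a)
                if v == 0:
                    return False
                if v == 1:
                    continue
                self.trail_lim.append(len(self.trail))
                self._enqueue(a, None)
                if self.propagate() is not None:
                    return False
            return None

        if apply_assumptions() is False:
            self._cancel_until(0)
            return False
        n_assumed = len(self.trail_lim)

        while True:
            confl = self.propagate()
            if confl is not None:
                self.stats["conflicts"] += 1
                conflicts_since_restart += 1
                if len(self.trail_lim) <= n_assumed:
                    # conflict under assumptions only
                    self._cancel_until(0)
                    if n_assumed == 0:
                        self.ok = False
                    return False
                learnt, bt = self._analyze(confl)
                self._cancel_until(max(bt, n_assumed))
                if bt < n_assumed:
                    # learnt clause reaches above the assumptions; re-root it
                    self._cancel_until(0)
                    self._record_root(learnt)
                    if apply_assumptions() is False:
                        self._cancel_until(0)
                        return False
                    n_assumed = len(self.trail_lim)
                else:
                    self._record(learnt)
                self.var_inc /= self.var_decay
                if conflict_budget is not None and \
                        self.stats["conflicts"] - start_conflicts > conflict_budget:
                    self._cancel_until(0)
                    return None
                if deadline is not None and time.monotonic() > deadline:
                    self._cancel_until(0)
                    return None
                continue
            if conflicts_since_restart >= restart_lim:
                restart_i += 1
                restart_lim = 100 * _luby(restart_i)
                conflicts_since_restart = 0
                self._cancel_until(n_assumed)
                continue
            var = self._decide()
            if var == 0:
                return True  # full assignment
            self.stats["decisions"] += 1
            self.trail_lim.append(len(self.trail))
            self._enqueue(var if self.phase[var] else -var, None)

    def _record_root(self, learnt: List[int]) -> None:
        # add a learnt clause at decision level 0
        sub = [q for q in learnt if self.value_lit(q) != 0]
        if not sub:
            self.ok = False
            return
        if len(sub) == 1:
            self._enqueue(sub[0], None)
            self.propagate()
            return
        ci = len(self.clauses)
        self.clauses.append(sub)
        self.watches[_widx(sub[0])].append(ci)
        self.watches[_widx(sub[1])].append(ci)

    # -- model extraction ---------------------------------------------------
    def model(self) -> List[int]:
        """Assignment after a satisfiable solve, as a list of literals."""
        return [v if self.assigns[v] == 1 else -v
                for v in range(1, self.n_vars + 1)
                if self.assigns[v] != UNASSIGNED]

    def value(self, var: int) -> bool:
        return self.assigns[var] == 1
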