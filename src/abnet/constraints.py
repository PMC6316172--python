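"""Experimental observations as trajectory constraints.

An :class:`ExperimentConstraint` encodes one experiment: culture inputs and
perturbations (a :class:`~abnet.network.PerturbationSchedule`), a discretised
initial state, and one or more expectations about the bounded synchronous
trajectory -- a partial state that must be reached, never reached, reached and
held at a full fixed point, or sustained over the two final steps.  A
:class:`ComparativeConstraint` couples two experiments evaluated on the same
concrete model and orders their first-hitting steps.

Two independent routes evaluate the same semantics: ``check_experiment`` /
``check_comparative`` simulate a concrete model directly, while
``encode_experiment`` / ``encode_comparative`` emit CNF through a
:class:`~abnet.encoding.SynthesisEncoder`.  The synthesis engine always
re-simulates solver witnesses through the first route.

The module also ships the study system: the naive-pluripotency network roster
(11 transcription factors plus the signal-proximal nodes MEK/ERK and Tcf3 and
the culture inputs LIF/CH/PD), the discretised EpiSC / naive states, and the
six EpiSC-resetting constraints plus the Sall4 comparative constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .encoding import SynthesisEncoder, Trajectory
from .network import (Clamp, ConcreteModel, PerturbationSchedule, State,
                      apply_schedule, sync_step)

# Expectation modalities
REACHED = "reached"
NEVER = "never"
STABLE = "stable"          # partial state at the bound + full-state fixed point
SUSTAINED = "sustained"    # partial state at the two final steps only


@dataclass(frozen=True)
class Expectation:
    modality: str
    state: Tuple[Tuple[str, bool], ...]  # sorted (component, value) pairs
    step_from: int = 0
    step_to: Optional[int] = None  # None: the trajectory bound

    def __post_init__(self):
        if self.modality not in (REACHED, NEVER, STABLE, SUSTAINED):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def partial(self) -> Dict[str, bool]:
        return dict(self.state)


def partial_state(d: Mapping[str, bool]) -> Tuple[Tuple[str, bool], ...]:
    return tuple(sorted((k, bool(v)) for k, v in d.items()))


@dataclass(frozen=True)
class ExperimentConstraint:
    name: str
    schedule: PerturbationSchedule
    initial: Tuple[Tuple[str, bool], ...]
    expectations: Tuple[Expectation, ...]
    bound: int = 20

    @property
    def initial_state(self) -> Dict[str, bool]:
        return dict(self.initial)


@dataclass(frozen=True)
class ComparativeConstraint:
    """first-hitting-step(treated target) >= first-hitting-step(reference).

    Vacuously satisfied when the reference trajectory never reaches the
    target within the bound.  Both sub-experiments are evaluated on the same
    concrete model.
    """

    name: str
    treated: ExperimentConstraint
    reference: ExperimentConstraint
    target: Tuple[Tuple[str, bool], ...]


Constraint = Union[ExperimentConstraint, ComparativeConstraint]


def experiment(name: str, inputs: Mapping[str, bool],
               initial: Mapping[str, bool],
               expectations: Sequence[Expectation],
               clamps: Sequence[Clamp] = (),
               bound: int = 20) -> ExperimentConstraint:
    """Convenience constructor."""
    sched = PerturbationSchedule(dict(inputs), tuple(clamps))
    return ExperimentConstraint(name, sched, partial_state(initial),
                                tuple(expectations), bound)


# ---------------------------------------------------------------------------
# Simulation-side semantics
# ---------------------------------------------------------------------------

def _matches(state: Mapping[str, bool], partial: Mapping[str, bool]) -> bool:
    return all(state[k] == v for k, v in partial.items())


def _simulate(model: ConcreteModel, con: ExperimentConstraint) -> List[State]:
    """States 0 .. bound+1 (one probe step past the bound)."""
    states = [apply_schedule(model, con.initial_state, con.schedule, 0)]
    for t in range(con.bound + 1):
        states.append(sync_step(model, states[-1], con.schedule, t))
    return states

def check_expectation(states: List[State], exp: Expectation, bound: int) -> bool:
    part = exp.partial
    hi = bound if exp.step_to is None else min(exp.step_to, bound)
    lo = exp.step_from
    if exp.modality == REACHED:
        return any(_matches(states[t], part) for t in range(lo, hi + 1))
    if exp.modality == NEVER:
        return not any(_matches(states[t], part) for t in range(lo, hi + 1))
    if exp.modality == STABLE:
        return _matches(states[bound], part) and states[bound] == states[bound + 1]
    if exp.modality == SUSTAINED:
        return _matches(states[bound - 1], part) and _matches(states[bound], part)
    raise AssertionError


def check_experiment(model: ConcreteModel, con: ExperimentConstraint) -> bool:
    states = _simulate(model, con)
    return all(check_expectation(states, e, con.bound) for e in con.expectations)


def first_hit(model: ConcreteModel, con: ExperimentConstraint,
              target: Mapping[str, bool]) -> Optional[int]:
    states = _simulate(model, con)
    for t in range(con.bound + 1):
        if _matches(states[t], target):
            return t
    return None


def check_comparative(model: ConcreteModel, con: ComparativeConstraint) -> bool:
    target = dict(con.target)
    fh_ref = first_hit(model, con.reference, target)
    if fh_ref is None:
        return True
    fh_tr = first_hit(model, con.treated, target)
    return fh_tr is None or fh_tr >= fh_ref


def check_constraint(model: ConcreteModel, con: Constraint) -> bool:
    if isinstance(con, ComparativeConstraint):
        return check_comparative(model, con)
    return check_experiment(model, con)


# ---------------------------------------------------------------------------
# SAT-side semantics
# ---------------------------------------------------------------------------

def encode_expectation(enc: SynthesisEncoder, traj: Trajectory,
                       exp: Expectation) -> int:
    part = exp.partial
    hi = traj.bound if exp.step_to is None else min(exp.step_to, traj.bound)
    lo = exp.step_from
    if exp.modality == REACHED:
        return enc.reached_in(traj, part, lo, hi)
    if exp.modality == NEVER:
        return enc.never_in(traj, part, lo, hi)
    if exp.modality == STABLE:
        return enc.stable_in(traj, part)
    if exp.modality == SUSTAINED:
        return enc.sustained_in(traj, part)
    raise AssertionError


def encode_experiment(enc: SynthesisEncoder, con: ExperimentConstraint,
                      assert_expectations: bool = True) -> Trajectory:
    traj = enc.add_trajectory(con.name, con.schedule, con.initial_state,
                              con.bound)
    if assert_expectations:
        for e in con.expectations:
            enc.assert_lit(encode_expectation(enc, traj, e))
    return traj


def encode_comparative(enc: SynthesisEncoder, con: ComparativeConstraint) -> None:
    tr_t = encode_experiment(enc, con.treated)
    tr_r = encode_experiment(enc, con.reference)
    target = dict(con.target)
    hit_t = enc.hit_by(tr_t, target)
    hit_r = enc.hit_by(tr_r, target)
    ref_never = -hit_r[tr_r.bound]
    for t in range(min(tr_t.bound, tr_r.bound) + 1):
        enc.solver.add_clause([ref_never, -hit_t[t], hit_r[t]])


def encode_constraints(enc: SynthesisEncoder,
                       constraints: Sequence[Constraint]) -> None:
    for con in constraints:
        if isinstance(con, ComparativeConstraint):
            encode_comparative(enc, con)
        else:
            encode_experiment(enc, con)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_bulk(expr: Mapping[str, float],
                    esc_reference: Mapping[str, float]) -> Dict[str, bool]:
    """Gene High iff its expression is at least 0.5x its level in naive ESCs
    (inclusive boundary)."""
    out = {}
    for gene, ref in esc_reference.items():
        if ref <= 0:
            raise ValueError(f"non-positive ESC reference for {gene}")
        if gene in expr:
            out[gene] = expr[gene] >= 0.5 * ref
    return out


def discretize_single_cell(log_expr, random_state: int = 0):
    """Per-gene 2-means discretization of log10 single-cell expression.

    Parameters
    ----------
    log_expr : pandas.DataFrame
        cells x genes matrix of log10-transformed expression.

    Returns
    -------
    (binary DataFrame, thresholds Series, degenerate dict)
        Cells in the higher-centroid cluster are High; the threshold is the
        midpoint between the two centroids.  Genes with a single distinct
        value are all-Low and flagged degenerate.
    """
    import pandas as pd
    from sklearn.cluster import KMeans

    binary = pd.DataFrame(False, index=log_expr.index, columns=log_expr.columns)
    thresholds = pd.Series(np.nan, index=log_expr.columns)
    degenerate = {}
    for gene in log_expr.columns:
        vals = log_expr[gene].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size < 2:
            raise ValueError(f"gene {gene}: need >=2 cells with defined expression")
        if np.unique(finite).size < 2:
            degenerate[gene] = True
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
        labels = km.fit_predict(finite.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        high_cluster = int(np.argmax(centers))
        thresholds[gene] = float(centers.mean())
        mask = np.isfinite(vals)
        binary.loc[mask, gene] = labels == high_cluster
        degenerate[gene] = False
    return binary, thresholds, degenerate


# ---------------------------------------------------------------------------
# The study system: naive-pluripotency resetting
# ---------------------------------------------------------------------------

#: Core transcription factors of the naive-pluripotency network.
CORE_TFS = ("Oct4", "Sox2", "Nanog", "Esrrb", "Klf2", "Klf4", "Tbx3",
            "Tfcp2l1", "Gbx2", "Sall4", "Stat3")
#: Signal-proximal components (targets of the culture inputs).
SIGNAL_NODES = ("MEKERK", "Tcf3")
#: Culture inputs: LIF cytokine, GSK3 inhibitor (CH), MEK inhibitor (PD).
INPUTS = ("LIF", "CH", "PD")

TWO_I_LIF = {"LIF": True, "CH": True, "PD": True}
TWO_I = {"LIF": False, "CH": True, "PD": True}
LIF_CH = {"LIF": True, "CH": True, "PD": False}


def state_library() -> Dict[str, Dict[str, bool]]:
    """Named discretised states.

    ``naive_ESC``: every core TF High (the target of resetting; the
    signal-proximal nodes follow the culture inputs and are not part of the
    target).  ``GOF18_EpiSC``: Oct4, Sox2 and Sall4 High among the TFs, with
    MEK/ERK and Tcf3 High as in FGF/Activin culture.  ``all_off``: every gene
    Low.
    """
    naive = {g: True for g in CORE_TFS}
    episc = {g: g in ("Oct4", "Sox2", "Sall4") for g in CORE_TFS}
    episc.update({"MEKERK": True, "Tcf3": True})
    all_off = {g: False for g in CORE_TFS + SIGNAL_NODES}
    return {"naive_ESC": naive, "GOF18_EpiSC": episc, "all_off": all_off}


def builtin_resetting_constraints() -> Tuple[List[ExperimentConstraint],
                                             ComparativeConstraint]:
    """The six EpiSC-resetting constraints plus the Sall4 comparative.

    1. Control: from the all-off state, 2i+LIF alone never induces the naive
       state.
    2. EpiSC in 2i+LIF: resetting reaches the naive state and stabilises.
    3. EpiSC in 2i only: the naive state is never reached.
    4. EpiSC in 2i with forced Tfcp2l1: key naive genes are sustained at the
       two final steps (Stat3 is LIF-dependent and excluded from the target,
       which is why the full final state is not pinned and the two-step
       variant is used).
    5. Nanog-knockout EpiSC in 2i+LIF: the naive state (minus the clamped
       Nanog itself) is never reached.
    6. Nanog-knockout EpiSC in LIF+CH: Oct4, Esrrb, Klf2, Tfcp2l1, Klf4 and
       Stat3 all become active at some step.

    The Sall4 comparative constraint: with Sall4 expression imposed, an EpiSC
    does not reach the naive state at an earlier step than without.
    """
    lib = state_library()
    naive, episc, all_off = lib["naive_ESC"], lib["GOF18_EpiSC"], lib["all_off"]

    c1 = experiment("control_all_off_2iLIF", TWO_I_LIF, all_off,
                    [Expectation(NEVER, partial_state(naive))])
    c2 = experiment("EpiSC_2iLIF", TWO_I_LIF, episc,
                    [Expectation(STABLE, partial_state(naive))])
    c3 = experiment("EpiSC_2i_only", TWO_I, episc,
                    [Expectation(NEVER, partial_state(naive))])
    naive_no_stat3 = {g: v for g, v in naive.items() if g != "Stat3"}
    c4 = experiment("EpiSC_2i_Tfcp2l1_forced", TWO_I, episc,
                    [Expectation(SUSTAINED, partial_state(naive_no_stat3))],
                    clamps=[Clamp("Tfcp2l1", True)])
    naive_no_nanog = {g: v for g, v in naive.items() if g != "Nanog"}
    c5 = experiment("NanogKO_EpiSC_2iLIF", TWO_I_LIF, episc,
                    [Expectation(NEVER, partial_state(naive_no_nanog))],
                    clamps=[Clamp("Nanog", False)])
    six_genes = {g: True for g in
                 ("Oct4", "Esrrb", "Klf2", "Tfcp2l1", "Klf4", "Stat3")}
    c6 = experiment("NanogKO_EpiSC_LIFCH", LIF_CH, episc,
                    [Expectation(REACHED, partial_state(six_genes))],
                    clamps=[Clamp("Nanog", False)])

    treated = experiment("Sall4_forced_2iLIF", TWO_I_LIF, episc, [],
                         clamps=[Clamp("Sall4", True)])
    reference = experiment("Sall4_control_2iLIF", TWO_I_LIF, episc, [])
    sall4 = ComparativeConstraint("Sall4_no_faster", treated, reference,
                                  partial_state(naive))
    return [c1, c2, c3, c4, c5, c6], sall4


def builtin_maintenance_constraints() -> List[ExperimentConstraint]:
    """Synthetic reconstruction of maintenance-era behaviours.

    The full maintenance constraint corpus lives in the original
    supplementary model files and is not printed in the resetting study;
    these four constraints reconstruct its characteristic shapes: ESCs
    self-renew in 2i+LIF (the naive state is a stable attractor), the naive
    state collapses on signal withdrawal, and Oct4 or Sox2 loss collapses it
    even in 2i+LIF.  They are a stand-in for, not a copy of, the published
    set.
    """
    lib = state_library()
    naive = lib["naive_ESC"]
    initial = dict(naive)
    initial.update({"MEKERK": False, "Tcf3": False})  # 2i+LIF culture
    no_inputs = {"LIF": False, "CH": False, "PD": False}
    m1 = experiment("ESC_2iLIF_maintained", TWO_I_LIF, initial,
                    [Expectation(STABLE, partial_state(naive))])
    m2 = experiment("ESC_withdrawal_collapse", no_inputs, initial,
                    [Expectation(NEVER, partial_state(naive), 12, 20)])
    naive_no_oct4 = {g: v for g, v in naive.items() if g != "Oct4"}
    m3 = experiment("ESC_Oct4KO_collapse", TWO_I_LIF, initial,
                    [Expectation(NEVER, partial_state(naive_no_oct4), 12, 20)],
                    clamps=[Clamp("Oct4", False)])
    naive_no_sox2 = {g: v for g, v in naive.items() if g != "Sox2"}
    m4 = experiment("ESC_Sox2KO_collapse", TWO_I_LIF, initial,
                    [Expectation(NEVER, partial_state(naive_no_sox2), 12, 20)],
                    clamps=[Clamp("Sox2", False)])
    return [m1, m2, m3, m4]
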