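"""The study system: a reconstruction of the naive-pluripotency ABN.

Eleven core transcription factors (Oct4, Sox2, Nanog, Esrrb, Klf2, Klf4,
Tbx3, Tfcp2l1, Gbx2, Sall4, Stat3), the signal-proximal nodes MEK/ERK and
Tcf3, and the culture inputs LIF, CH (GSK3 inhibition) and PD (MEK
inhibition).  Definite interactions are the signal axes and the direct
regulations established in the literature (LIF/Stat3 with its effectors
Tfcp2l1, Klf4 and Gbx2; CH relieving Tcf3 repression of Tfcp2l1 and Esrrb;
PD relieving MEK/ERK; the definite Esrrb activators Sall4, Nanog and
Tfcp2l1); optional interactions are a correlation-style bidirectional mesh
among the core factors.

This network is a *synthetic reconstruction* assembled from the published
figure roster and interaction descriptions, not the original supplementary
model file; analyses on it characterise the reconstruction.

MEK/ERK and Tcf3 carry a positive self-loop: with update rules that demand
an active activator, a component that should stay High until its inhibitor
arrives needs a self-sustaining input.  Under resetting conditions both
start High (FGF/Activin culture) and are extinguished by PD/CH.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Tuple

from .constraints import (ComparativeConstraint, Constraint,
                          ExperimentConstraint,
                          builtin_maintenance_constraints,
                          builtin_resetting_constraints,
                          CORE_TFS, INPUTS, SIGNAL_NODES, state_library)
from .network import AbstractNetwork, Component, GENE, Interaction, SIGNAL

_DEFINITE: Tuple[Tuple[str, str, bool], ...] = (
    ("LIF", "Stat3", True),
    ("CH", "Tcf3", False),
    ("PD", "MEKERK", False),
    ("Tcf3", "Tcf3", True),
    ("MEKERK", "MEKERK", True),
    ("Stat3", "Tfcp2l1", True),
    ("Stat3", "Klf4", True),
    ("Stat3", "Gbx2", True),
    ("Esrrb", "Tfcp2l1", True),
    ("Tcf3", "Tfcp2l1", False),
    ("Sall4", "Esrrb", True),
    ("Nanog", "Esrrb", True),
    ("Tfcp2l1", "Esrrb", True),
    ("Tcf3", "Esrrb", False),
    ("MEKERK", "Nanog", False),
)

_OPTIONAL: Tuple[Tuple[str, str, bool], ...] = (
    ("Oct4", "Sox2", True), ("Sox2", "Oct4", True),
    ("Oct4", "Sall4", True), ("Sall4", "Oct4", True),
    ("Sox2", "Sall4", True), ("Sall4", "Sox2", True),
    ("Oct4", "Nanog", True), ("Nanog", "Oct4", True),
    ("Sox2", "Nanog", True), ("Nanog", "Sox2", True),
    ("Esrrb", "Oct4", True), ("Esrrb", "Sox2", True), ("Esrrb", "Sall4", True),
    ("MEKERK", "Esrrb", False),
    ("Tbx3", "Tfcp2l1", True), ("Gbx2", "Tfcp2l1", True),
    ("Klf2", "Tfcp2l1", True), ("Klf4", "Tfcp2l1", True),
    ("Tfcp2l1", "Nanog", True), ("Klf2", "Nanog", True),
    ("Oct4", "Klf2", True), ("MEKERK", "Klf2", False),
    ("Klf2", "Klf4", True), ("Esrrb", "Klf4", True), ("Nanog", "Klf4", True),
    ("Esrrb", "Tbx3", True), ("Klf4", "Tbx3", True), ("Tfcp2l1", "Tbx3", True),
    ("MEKERK", "Tbx3", False),
    ("Klf2", "Gbx2", True), ("Tfcp2l1", "Stat3", True),
)


def resetting_network() -> AbstractNetwork:
    """Build the reconstruction programmatically."""
    comps = [Component(n, SIGNAL) for n in INPUTS]
    comps += [Component(n, GENE) for n in CORE_TFS + SIGNAL_NODES]
    edges = [Interaction(s, t, p, True) for s, t, p in _DEFINITE]
    edges += [Interaction(s, t, p, False) for s, t, p in _OPTIONAL]
    return AbstractNetwork(comps, edges)


def load_fixture_network() -> AbstractNetwork:
    """The same reconstruction, from the packaged network file."""
    from .io import parse_network
    text = resources.files("abnet").joinpath(
        "fixtures/pluripotency.net").read_text()
    return parse_network(text)


def load_fixture_experiments() -> List[Constraint]:
    """The six resetting constraints + the Sall4 comparative, from file."""
    from .io import parse_experiments
    text = resources.files("abnet").joinpath(
        "fixtures/resetting.exp").read_text()
    return parse_experiments(text)


def resetting_constraints() -> List[Constraint]:
    six, sall4 = builtin_resetting_constraints()
    return [*six, sall4]


def load_maintenance_experiments() -> List[Constraint]:
    """Reconstructed maintenance-era constraints, from the packaged file."""
    from .io import parse_experiments
    text = resources.files("abnet").joinpath(
        "fixtures/maintenance.exp").read_text()
    return parse_experiments(text)


def full_constraints() -> List[Constraint]:
    """Maintenance reconstruction + the six resetting constraints + the
    Sall4 comparative."""
    return [*builtin_maintenance_constraints(), *resetting_constraints()]
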