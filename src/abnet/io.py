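"""Readers and writers for network, experiment and result files.

Two hand-editable line-oriented formats:

Network file (``.net``)::

    # components
    component LIF signal
    component Oct4 gene conditions=0-8
    # interactions: -> activation, -| inhibition
    LIF -> Stat3 definite
    Oct4 -> Sox2 optional

Experiments file (``.exp``)::

    experiment EpiSC_2iLIF
      bound 20
      inputs LIF=on CH=on PD=on
      force Tfcp2l1 high from=0 to=20
      initial Oct4=high Sox2=high Nanog=low
      expect stable state Oct4=high Sox2=high
      expect never step 0..20 state Nanog=high

    comparative Sall4_no_faster treated=Sall4_forced reference=Sall4_control \
state Oct4=high

A JSON mirror of the network schema is accepted (``.json``).  Both formats
round-trip exactly: parse(write(x)) == x.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .constraints import (ComparativeConstraint, Constraint, Expectation,
                          ExperimentConstraint, NEVER, REACHED, STABLE,
                          SUSTAINED, partial_state)
from .network import (AbstractNetwork, Clamp, Component, GENE, Interaction,
                      N_CONDITIONS, PerturbationSchedule, SIGNAL)


class ParseError(ValueError):
    def __init__(self, msg: str, line_no: Optional[int] = None):
        where = f" (line {line_no})" if line_no is not None else ""
        super().__init__(f"{msg}{where}")
        self.line_no = line_no


@dataclass
class RunConfig:
    """Run-wide settings shared by the CLI subcommands."""
    solver_timeout: float = 300.0
    trajectory_bound: int = 20
    seed: int = 0
    threshold_grid: Optional[List[float]] = None
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.trajectory_bound < 1:
            raise ValueError("trajectory bound must be >= 1")


# ---------------------------------------------------------------------------
# condition sets
# ---------------------------------------------------------------------------

def _parse_conditions(spec: str, line_no: int) -> frozenset:
    out = set()
    for part in spec.split(","):
        if "-" in part:
            lo, hi = part.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        elif part:
            out.add(int(part))
    if not out or not all(0 <= c < N_CONDITIONS for c in out):
        raise ParseError(f"bad condition set {spec!r}", line_no)
    return frozenset(out)


def _format_conditions(conds: frozenset) -> str:
    # compact run-length form, e.g. 0-3,5,7-8
    vals = sorted(conds)
    runs: List[Tuple[int, int]] = []
    for v in vals:
        if runs and v == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], v)
        else:
            runs.append((v, v))
    return ",".join(f"{a}-{b}" if a != b else f"{a}" for a, b in runs)


# ---------------------------------------------------------------------------
# network files
# ---------------------------------------------------------------------------

def _canonical_condition_index(bits: str, line_no: int) -> int:
    """Map an explicit 9-cell truth table (activator-major, '0'/'1') to the
    canonical condition index.  Lets files written against a tool whose
    numbering permutes the conditions declare their tables explicitly."""
    from .network import REGULATION_CONDITIONS, NONE, SOME, ALL
    if len(bits) != 9 or set(bits) - {"0", "1"}:
        raise ParseError(f"condition table must be 9 binary cells, "
                         f"got {bits!r}", line_no)
    cells = tuple(b == "1" for b in bits)
    for cond in REGULATION_CONDITIONS:
        ours = tuple(cond.table[(a, r)]
                     for a in (NONE, SOME, ALL) for r in (NONE, SOME, ALL))
        if ours == cells:
            return cond.index
    raise ParseError(f"table {bits!r} is not one of the nine canonical "
                     "regulation conditions", line_no)


def parse_network(text: str) -> AbstractNetwork:
    components: List[Component] = []
    interactions: List[Interaction] = []
    names = set()
    remap: Dict[int, int] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0] == "conditiontable":
            if len(tokens) != 3:
                raise ParseError("conditiontable needs INDEX and 9 cells",
                                 line_no)
            remap[int(tokens[1])] = _canonical_condition_index(tokens[2],
                                                               line_no)
            continue
        if tokens[0] == "component":
            if len(tokens) < 3 or tokens[2] not in (GENE, SIGNAL):
                raise ParseError(f"malformed component line {raw!r}", line_no)
            name, role = tokens[1], tokens[2]
            conds = frozenset(range(N_CONDITIONS))
            for extra in tokens[3:]:
                if extra.startswith("conditions="):
                    conds = _parse_conditions(extra[len("conditions="):],
                                              line_no)
                else:
                    raise ParseError(f"unknown token {extra!r}", line_no)
            components.append(Component(name, role, conds))
            names.add(name)
        elif len(tokens) == 4 and tokens[1] in ("->", "-|"):
            src, sign, tgt, kind = tokens
            if kind not in ("definite", "optional"):
                raise ParseError(f"unknown interaction kind {kind!r}", line_no)
            for nm in (src, tgt):
                if nm not in names:
                    raise ParseError(f"unknown component {nm!r}", line_no)
            interactions.append(Interaction(src, tgt, sign == "->",
                                            kind == "definite"))
        else:
            raise ParseError(f"unparseable line {raw!r}", line_no)
    if remap:
        components = [
            c if c.role == SIGNAL else Component(
                c.name, c.role,
                frozenset(remap.get(i, i) for i in c.allowed_conditions))
            for c in components]
    return AbstractNetwork(components, interactions)


def format_network(net: AbstractNetwork) -> str:
    lines = []
    for c in net.components:
        if c.role == SIGNAL:
            lines.append(f"component {c.name} signal")
        else:
            lines.append(f"component {c.name} gene "
                         f"conditions={_format_conditions(c.allowed_conditions)}")
    for i in net.interactions:
        arrow = "->" if i.positive else "-|"
        kind = "definite" if i.definite else "optional"
        lines.append(f"{i.source} {arrow} {i.target} {kind}")
    return "\n".join(lines) + "\n"


def network_to_json(net: AbstractNetwork) -> dict:
    return {
        "components": [
            {"name": c.name, "role": c.role,
             "allowed_conditions": sorted(c.allowed_conditions)}
            for c in net.components],
        "interactions": [
            {"source": i.source, "target": i.target, "sign": i.sign,
             "definiteness": "definite" if i.definite else "optional"}
            for i in net.interactions],
    }


def network_from_json(obj: Mapping) -> AbstractNetwork:
    comps = [Component(c["name"], c.get("role", GENE),
                       frozenset(c.get("allowed_conditions",
                                       range(N_CONDITIONS))))
             for c in obj["components"]]
    edges = [Interaction(i["source"], i["target"],
                         i["sign"] == "positive",
                         i.get("definiteness", "optional") == "definite")
             for i in obj["interactions"]]
    return AbstractNetwork(comps, edges)


def load_network(path) -> AbstractNetwork:
    text = open(path).read()
    if str(path).endswith(".json"):
        return network_from_json(json.loads(text))
    return parse_network(text)


def save_network(net: AbstractNetwork, path) -> None:
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(network_to_json(net), fh, indent=1)
            fh.write("\n")
        else:
            fh.write(format_network(net))


# ---------------------------------------------------------------------------
# experiments files
# ---------------------------------------------------------------------------

_HL = {"high": True, "low": False}


def _parse_state(tokens: Sequence[str], line_no: int) -> Dict[str, bool]:
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise ParseError(f"expected NAME=high|low, got {tok!r}", line_no)
        name, val = tok.split("=", 1)
        if val not in _HL:
            raise ParseError(f"expected high|low, got {val!r}", line_no)
        out[name] = _HL[val]
    return out


def _format_state(pairs: Tuple[Tuple[str, bool], ...]) -> str:
    return " ".join(f"{k}={'high' if v else 'low'}" for k, v in pairs)


def parse_experiments(text: str) -> List[Constraint]:
    experiments: Dict[str, ExperimentConstraint] = {}
    exp_order: List[str] = []
    comparatives: List[Tuple[str, str, str, Tuple, int]] = []
    cur: Optional[dict] = None

    def finish():
        nonlocal cur
        if cur is None:
            return
        con = ExperimentConstraint(
            cur["name"],
            PerturbationSchedule(cur["inputs"], tuple(cur["clamps"])),
            partial_state(cur["initial"]),
            tuple(cur["expect"]), cur["bound"])
        experiments[cur["name"]] = con
        exp_order.append(cur["name"])
        cur = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0]
        if kw == "experiment":
            finish()
            if len(tokens) != 2:
                raise ParseError("experiment needs exactly one name", line_no)
            cur = {"name": tokens[1], "inputs": {}, "clamps": [],
                   "initial": {}, "expect": [], "bound": 20}
        elif kw == "comparative":
            finish()
            m = dict(tok.split("=", 1) for tok in tokens[2:4])
            if len(tokens) < 6 or "treated" not in m or "reference" not in m \
                    or tokens[4] != "state":
                raise ParseError(f"malformed comparative line {raw!r}", line_no)
            state = _parse_state(tokens[5:], line_no)
            comparatives.append((tokens[1], m["treated"], m["reference"],
                                 partial_state(state), line_no))
        elif cur is None:
            raise ParseError(f"directive outside an experiment: {raw!r}",
                             line_no)
        elif kw == "bound":
            cur["bound"] = int(tokens[1])
        elif kw == "inputs":
            for tok in tokens[1:]:
                name, val = tok.split("=", 1)
                if val not in ("on", "off"):
                    raise ParseError(f"expected on|off, got {val!r}", line_no)
                cur["inputs"][name] = val == "on"
        elif kw == "force":
            if len(tokens) < 3 or tokens[2] not in _HL:
                raise ParseError(f"malformed force line {raw!r}", line_no)
            start, end = 0, None
            for extra in tokens[3:]:
                k, v = extra.split("=", 1)
                if k == "from":
                    start = int(v)
                elif k == "to":
                    end = int(v)
                else:
                    raise ParseError(f"unknown force option {extra!r}", line_no)
            cur["clamps"].append(Clamp(tokens[1], _HL[tokens[2]], start, end))
        elif kw == "initial":
            cur["initial"].update(_parse_state(tokens[1:], line_no))
        elif kw == "expect":
            modality = tokens[1]
            if modality not in (REACHED, NEVER, STABLE, SUSTAINED):
                raise ParseError(f"unknown modality {modality!r}", line_no)
            rest = tokens[2:]
            step_from, step_to = 0, None
            if rest and rest[0] == "step":
                rng = rest[1]
                m = re.fullmatch(r"(\d+)\.\.(\d+|end)", rng)
                if not m:
                    raise ParseError(f"bad step range {rng!r}", line_no)
                step_from = int(m.group(1))
                step_to = None if m.group(2) == "end" else int(m.group(2))
                rest = rest[2:]
            if not rest or rest[0] != "state":
                raise ParseError("expect needs a state clause", line_no)
            state = _parse_state(rest[1:], line_no)
            cur["expect"].append(Expectation(modality, partial_state(state),
                                             step_from, step_to))
        else:
            raise ParseError(f"unknown directive {kw!r}", line_no)
    finish()

    consumed = set()
    out: List[Constraint] = []
    comps: List[ComparativeConstraint] = []
    for name, tr, ref, target, line_no in comparatives:
        for key in (tr, ref):
            if key not in experiments:
                raise ParseError(f"comparative references unknown "
                                 f"experiment {key!r}", line_no)
        comps.append(ComparativeConstraint(name, experiments[tr],
                                           experiments[ref], target))
        consumed.update((tr, ref))
    out.extend(experiments[n] for n in exp_order if n not in consumed)
    out.extend(comps)
    return out


def format_experiments(constraints: Sequence[Constraint]) -> str:
    chunks: List[str] = []
    comp_lines: List[str] = []

    def emit(con: ExperimentConstraint) -> None:
        lines = [f"experiment {con.name}", f"  bound {con.bound}"]
        if con.schedule.inputs:
            ins = " ".join(f"{k}={'on' if v else 'off'}"
                           for k, v in sorted(con.schedule.inputs.items()))
            lines.append(f"  inputs {ins}")
        for cl in con.schedule.clamps:
            s = f"  force {cl.component} {'high' if cl.value else 'low'}"
            if cl.start != 0:
                s += f" from={cl.start}"
            if cl.end is not None:
                s += f" to={cl.end}"
            lines.append(s)
        if con.initial:
            lines.append(f"  initial {_format_state(con.initial)}")
        for e in con.expectations:
            s = f"  expect {e.modality}"
            if e.modality in (REACHED, NEVER):
                hi = "end" if e.step_to is None else str(e.step_to)
                s += f" step {e.step_from}..{hi}"
            s += f" state {_format_state(e.state)}"
            lines.append(s)
        chunks.append("\n".join(lines))

    for con in constraints:
        if isinstance(con, ComparativeConstraint):
            emit(con.treated)
            emit(con.reference)
            comp_lines.append(
                f"comparative {con.name} treated={con.treated.name} "
                f"reference={con.reference.name} state "
                f"{_format_state(con.target)}")
        else:
            emit(con)
    return "\n\n".join(chunks + comp_lines) + "\n"


def load_experiments(path) -> List[Constraint]:
    return parse_experiments(open(path).read())


def save_experiments(constraints: Sequence[Constraint], path) -> None:
    with open(path, "w") as fh:
        fh.write(format_experiments(constraints))


# ---------------------------------------------------------------------------
# expression datasets
# ---------------------------------------------------------------------------

def load_expression_csv(path, condition_label: str = "",
                        source_label: str = ""):
    """Genes-as-rows CSV/TSV -> ExpressionDataset."""
    import pandas as pd
    from .inference import ExpressionDataset
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionDataset(df, condition_label or str(path),
                             source_label or str(path))


def save_expression_csv(dataset, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    dataset.matrix.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def model_to_json(model) -> dict:
    return {
        "chosen_optional": [
            {"source": i.source, "target": i.target, "sign": i.sign}
            for i in sorted(model.chosen_optional,
                            key=lambda i: (i.source, i.target, i.sign))],
        "conditions": dict(sorted(model.conditions.items())),
        "n_interactions": model.n_interactions(),
    }


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
        fh.write("\n")
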