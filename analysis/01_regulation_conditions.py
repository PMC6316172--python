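"""Enumerate the canonical regulation conditions.

Derives the nine monotone Boolean update rules on the activator/repressor
availability grid (none/some/all) that require at least one active
activator, orders them from least to most permissive, and writes the full
truth tables.  These are the per-component update-rule choices available to
every concrete model.
"""

import json
from pathlib import Path

from abnet.network import ALL, NONE, SOME, enumerate_regulation_conditions

LEVEL_NAMES = {NONE: "none", SOME: "some", ALL: "all"}
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    conds = enumerate_regulation_conditions()
    rows = []
    for c in conds:
        table = {f"act={LEVEL_NAMES[a]},rep={LEVEL_NAMES[r]}": c.table[(a, r)]
                 for a in (NONE, SOME, ALL) for r in (NONE, SOME, ALL)}
        rows.append({"index": c.index, "n_active_cells": c.n_true(),
                     "table": table})
        print(f"condition {c.index}: {c.n_true()} activating cell(s)")
    print(f"\n{len(conds)} regulation conditions; condition 0 activates only "
          "with all activators and no repressors, condition 8 with any "
          "activator regardless of repression.")
    OUT.mkdir(exist_ok=True)
    (OUT / "regulation_conditions.json").write_text(
        json.dumps({"n_conditions": len(conds), "conditions": rows},
                   indent=1) + "\n")
    print(f"-> {OUT / 'regulation_conditions.json'}")


if __name__ == "__main__":
    main()
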