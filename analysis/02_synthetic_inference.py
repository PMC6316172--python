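"""Correlation-based interaction inference on synthetic ground truth.

Plants a known signed network, simulates condition-specific expression,
calls possible interactions at the planted threshold, and measures recovery.
Two regimes:

* the default (tree-structured) generator, where multi-regulator genes cap
  pairwise correlation near 1/sqrt(2) and recall plateaus below one -- the
  structural identifiability limit of threshold-based calling;
* the matching structure (disjoint regulator-target pairs, no indirect
  paths), where precision and recall reach 1 at low noise.

Also runs the maximal-satisfiable-threshold search against constraints
generated from the ground truth's own behaviour.
"""

import json
from pathlib import Path

import numpy as np

from abnet.inference import (call_possible_interactions,
                             compute_correlation_profiles,
                             find_max_threshold)
from abnet.network import AbstractNetwork
from abnet.synthetic import (generate_observations, sample_ground_truth,
                             simulate_expression)

OUT = Path(__file__).resolve().parents[1] / "results"


def pairs(edges):
    return {(frozenset((e.source, e.target)), e.positive) for e in edges}


def recovery(gt, datasets, threshold):
    planted = pairs(gt.planted_interactions())
    calls = pairs(call_possible_interactions(
        compute_correlation_profiles(datasets), threshold))
    tp = len(planted & calls)
    return {"recall": tp / len(planted),
            "precision": tp / len(calls) if calls else None,
            "n_planted": len(planted), "n_called": len(calls)}


def main():
    out = {}

    print("== default (tree) generator, emission noise sd 0.2 ==")
    per_seed = []
    for gseed in (7, 8, 9):
        gt = sample_ground_truth(12, 3, 25, seed=gseed)
        ds = simulate_expression(gt, 7, 20, seed=3)
        rec = recovery(gt, ds, gt.planted_threshold)
        per_seed.append(rec)
        print(f"  network seed {gseed}: recall {rec['recall']:.2f}, "
              f"precision {rec['precision']:.2f} "
              f"({rec['n_called']} calls / {rec['n_planted']} planted)")
    out["tree_default"] = per_seed
    print("  multi-regulator genes bound pairwise |r| by 1/sqrt(2): recall "
          "plateaus below 1 by construction, and chain neighbours inflate "
          "the call set. Constraint-based synthesis, not the correlation "
          "screen, carries model selection.")

    print("\n== matching structure, low noise: sharp recovery ==")
    sharp = []
    for seed in (1, 2, 3):
        gt = sample_ground_truth(12, 3, 25, seed=seed, noise_sd=0.02,
                                 structure="matching")
        gt.p_flip = 0.02
        ds = simulate_expression(gt, 7, 100, seed=seed + 10)
        rec = recovery(gt, ds, gt.planted_threshold)
        sharp.append(rec)
        print(f"  seed {seed}: recall {rec['recall']:.2f}, "
              f"precision {rec['precision']:.2f}")
    out["matching_low_noise"] = sharp

    print("\n== maximal satisfiable threshold ==")
    gt = sample_ground_truth(10, 3, 20, seed=11, noise_sd=0.05,
                             structure="matching", conditions_per_gene=2)
    datasets = simulate_expression(gt, 7, 60, seed=12)
    cons, _ = generate_observations(gt, n_experiments=3, seed=13)
    base = AbstractNetwork(gt.network.components,
                           gt.network.definite_interactions)
    grid = [0.3, 0.45, gt.planted_threshold, 0.9, 0.97]
    th, abn, res = find_max_threshold(datasets, base, cons,
                                      candidate_grid=grid)
    print(f"  grid {grid} -> threshold {th} "
          f"({len(abn.optional_interactions)} possible interactions, "
          f"{res.status})")
    out["threshold_search"] = {"grid": grid, "threshold": th,
                               "n_possible": len(abn.optional_interactions),
                               "status": res.status}

    OUT.mkdir(exist_ok=True)
    (OUT / "synthetic_inference.json").write_text(
        json.dumps(out, indent=1) + "\n")
    print(f"-> {OUT / 'synthetic_inference.json'}")


if __name__ == "__main__":
    main()
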