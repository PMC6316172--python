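# abnet — abstract Boolean network synthesis for gene regulatory programs

Cell-fate transitions such as the resetting of primed epiblast stem cells
(EpiSCs) to naive pluripotency are driven by a transcription-factor (TF)
network whose wiring is only partially known.  `abnet` implements an
automated-reasoning pipeline for this situation, for computational and stem
cell biologists who want models that are *provably* consistent with their
perturbation data rather than a single hand-tuned network:

1. **Abstract Boolean Network (ABN).**  Components (genes plus culture
   inputs LIF/CH/PD) are connected by *definite* signed interactions
   (established signal axes) and *optional* ones called from pairwise
   Pearson correlation of expression across culture conditions (a pair is
   possible-and-positive when at least one dataset's coefficient reaches a
   threshold and a strict majority of the remaining coefficients agrees in
   sign; calls are bidirectional because correlation cannot orient an
   edge).  With *n* optional interactions the ABN defines 2^n candidate
   topologies.
2. **Constrained ABN (cABN).**  Each gene updates by one of nine monotone
   *regulation conditions* over the availability (none/some/all) of its
   activators and repressors, always requiring an active activator;
   dynamics are synchronous and deterministic, unrolled to a 20-step bound.
   Experimental observations — reached / never-reached / stable /
   sustained discretised states under stated inputs and clamps — are
   compiled, together with all topology and rule choices, into CNF and
   handed to a built-in CDCL SAT solver.  The satisfying models form the
   cABN; every witness is re-simulated independently of the solver.
3. **All-models predictions.**  A hypothesis about an untested experiment
   is tested along with its null against the entire cABN: if every
   consistent model agrees, a definitive prediction is formulated
   (activation timing, factor essentiality, activation order,
   reprogramming-cocktail outcomes); disagreement is reported as
   *no prediction*.  Predictions are scored against outcome tables, and a
   single model (e.g. the interaction-minimal one) can be cross-validated
   under asynchronous updates.

A synthetic-data module generates ground-truth networks, condition-specific
expression, and observation sets so that every stage is testable without
downloads; `src/abnet/fixtures/` ships a reconstruction of the published
naive-pluripotency system (16 components) with the six EpiSC-resetting
constraints and a Sall4 no-faster comparative constraint.

## Worked example

```python
from abnet.pluripotency import resetting_network, resetting_constraints
from abnet.synthesis import synthesize, minimal_model
from abnet.constraints import state_library, TWO_I_LIF
from abnet.network import PerturbationSchedule, sync_trajectory

net  = resetting_network()          # 16 components, 15 definite + 31 optional
cons = resetting_constraints()      # six resetting behaviours + Sall4 comparative

res = synthesize(net, cons)
print(res.status)                    # satisfiable
print(res.witness.n_interactions())  # 30

mm = minimal_model(net, cons)
print(mm.n_interactions())           # 22

lib = state_library()
states, fixed = sync_trajectory(mm, lib["GOF18_EpiSC"],
                                PerturbationSchedule(dict(TWO_I_LIF)))
print(fixed, all(states[20][g] for g in lib["naive_ESC"]))  # True True
```

`satisfiable` means concrete models exist that reproduce all encoded
resetting behaviours at once; the witness instantiates 30 of the 46
candidate interactions, and the sparsest consistent model needs only 22.
The trajectory check replays EpiSC resetting on that minimal model: from
the discretised GOF18 EpiSC state in 2i+LIF it reaches a fixed point with
every naive-network TF High.

The numbered scripts under `analysis/` walk the full study:
`01` the nine regulation conditions, `02` correlation-based inference and
threshold search on synthetic ground truth, `03` the 20-seed soundness
chain, `04` characterisation of the resetting cABN (classification,
minimal model, deletion scan), `05` dynamic predictions over it, `06`
asynchronous cross-validation of the minimal model.  Outputs land in
`results/`.

## Command line

`abnet infer | synthesize | classify | predict | simulate-async |
make-synthetic | score` wrap the library over the repo's text formats
(`.net` networks, `.exp` experiments, CSV expression, JSON results); see
`abnet --help`.
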