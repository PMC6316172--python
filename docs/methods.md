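# Methods

`abnet` implements an automated-reasoning pipeline for gene regulatory
program discovery: build an *abstract Boolean network* (ABN) whose optional
interactions come from expression correlation, synthesize the set of
concrete Boolean models consistent with encoded experimental observations
(the *constrained ABN*, cABN), and interrogate the whole model set to
formulate dynamic predictions.  The study system is the transcription-factor
program of naive pluripotency: maintenance of mouse embryonic stem cells in
2i+LIF, resetting of primed epiblast stem cells (EpiSCs), and somatic
reprogramming.

## Model

**Components and interactions.**  A network has *gene* components and
clamp-only *signal* components (the culture inputs LIF, CH = GSK3
inhibition, PD = MEK inhibition).  Interactions are signed
(activation/repression) and either *definite* (present in every model) or
*optional*.  With *n* optional interactions the ABN implicitly defines 2^n
candidate topologies.

**Regulation conditions.**  Update rules are not tied to named regulators:
each gene is assigned one of nine *regulation conditions*, the monotone
Boolean functions on the 3x3 grid of activator/repressor availability
(none / some / all) that (i) output False with no active activator,
(ii) output True with all activators active and no repressor active, and
(iii) are non-decreasing in activator level and non-increasing in repressor
level.  Exactly nine such tables exist (the number of monotone maps on a
2x3 grid poset is C(5,2) = 10; removing the all-False map leaves 9); they
are ordered from least permissive (condition 0: all activators, no
repressors) to most permissive (condition 8: any activator, repression
ignored).  Availability levels count *instantiated* regulators in the
concrete model at hand, so "some" is unreachable for a gene with a single
instantiated regulator of a class.  Rules that activate without any
activator are out of scope.

**Dynamics.**  Synchronous and deterministic: every gene updates
simultaneously from its regulators' current values; signals and clamped
components take their scheduled values.  Forced expression is a clamp High
over the trajectory, knockdown/knockout a clamp Low; finite clamp windows
model transient (DOX-style) induction.  A trajectory runs to a bound of 20
steps (the experiment-encoding default throughout), plus one probe step so
stability can be read as `state(20) == state(21)`.

**Constraints.**  An experiment constraint is a culture-input setting,
perturbation clamps, a discretised initial state and expectations over the
bounded trajectory with four modalities: *reached* (partial state holds at
some step in a window), *never* (it holds at none), *stable* (it holds at
the bound and the final state is a full fixed point) and *sustained* (it
holds at the two final steps -- used when the full final state cannot be
pinned down, e.g. forced Tfcp2l1 in 2i, where Stat3 is LIF-dependent and
deliberately outside the target).  A comparative constraint couples two
experiments on shared model choices and demands the treated trajectory not
reach a target earlier than the reference; it is vacuously satisfied when
the reference never reaches the target within the bound.  Unspecified genes
in an initial state default to Low, which keeps *never* expectations sound
under deterministic updates.

**Discretisation.**  Bulk profiles: a gene is High iff its expression is at
least 0.5x its level in naive ESCs in 2i+LIF (inclusive).  Single-cell
profiles: per-gene 2-means clustering on log10 expression; cells in the
higher-centroid cluster are High and the reported threshold is the centroid
midpoint; genes with a single distinct value are flagged degenerate and set
Low.

## Synthesis engine

The bounded synthesis question -- does some choice of optional interactions
and per-gene conditions generate trajectories meeting every constraint --
is compiled to CNF: one variable per optional interaction, a one-hot block
per gene over its allowed conditions, and state variables for every
(experiment, component, step), with the transition relation unrolled to the
bound + 1.  Availability levels are encoded through "some active
instantiated regulator" / "all instantiated regulators active" literals;
each condition's truth table becomes one clause per grid cell.  All
experiments share the choice variables, so a satisfying assignment is one
concrete model consistent with everything at once.

The solver is a compact conflict-driven clause-learning (CDCL) SAT solver
(two watched literals, first-UIP learning, exponential VSIDS activity,
phase saving, Luby restarts, assumption literals, conflict/time budgets).
Because the trajectory variables are functionally determined by the choice
variables, branching is restricted to the choice variables, which keeps the
search in the combinatorial core (this cut the study-system solve from
minutes to seconds).  Every "satisfiable" verdict is backed by a witness
model that is re-simulated through the plain dynamics code, independently
of the solver; a mismatch raises.

On top of the base query sit: required/disallowed interaction
classification (remove or impose each optional edge individually and
re-test), used/unused condition classification, exact model counting by
blocking-clause enumeration, cardinality-minimal model search (sequential-
counter at-most-k ladder with a certificate of unsatisfiability one below
the optimum), component-deletion scans (constraints mentioning a deleted
component are projected or dropped), and a random-network control that
resamples interactions preserving the component roster and the
definite/optional x sign counts.

**Budgets and honesty.**  Proving an *all-models* statement means refuting
the entire consistent-model set.  On weakly constrained networks the CDCL
refutation degenerates into enumerating consistent models one conflict at a
time, which a pure-Python solver does at ~10-20 models/s; the study-system
reconstruction admits well over 2 x 10^4 consistent models, so some
all-model queries are genuinely out of budget.  Such queries run under a
per-query time budget and report *indeterminate*; they are never silently
resolved, and a timeout is never reported as unsatisfiable.

## Predictions

A hypothesis about an untested experiment is tested against the whole model
set together with its null: hypothesis holds in every model -> positive
prediction; in none -> negative; otherwise no prediction (and a
discriminating experiment).  Two interchangeable backends answer queries:
*enumerate* (list the consistent models once by blocking-clause iteration,
then answer each query by simulating every model -- exact and fast when the
set fits; a `brute` variant enumerates by exhaustive simulation, giving a
fully solver-independent route) and *sat* (reify the hypothesis in the
shared CNF and flip it with assumption literals -- scales past enumerable
sets, subject to the budget caveat above).  `auto` tries enumeration up to
a cap and falls back to SAT.

Query battery: steps to stabilise in a target (per-step hypothesis scan;
"stabilised at s" = target holds from s through the bound-plus-probe and
the final state is a fixed point), permanent activation step of one gene
(High from s through the probe step; the global fixed point is not
additionally required), activation-order queries (X always active before Y:
strict precedence -- simultaneous first activation counts as neither
preceding), paired-schedule efficiency comparison on first-hit steps
(configurable to first-stable), essentiality under knockdown (the clamped
gene is projected out of the target, else the query is vacuous), and
reprogramming-cocktail queries (all-off start, cocktail clamped High;
factors outside the roster are dropped with a warning).  Accuracy scoring
reports definitive-prediction accuracy and a conservative variant that
counts a no-prediction as incorrect, with its denominator stated; outcome
rows that match no prediction are listed, never dropped.

## Interaction inference

For every unordered gene pair, one Pearson coefficient per
culture-condition dataset, computed on log10-transformed expression
(levels span orders of magnitude; linear-scale Pearson would be dominated
by the high mode's multiplicative noise).  A pair is called possible and
positive if at least one coefficient reaches the threshold and a strict
majority of the remaining defined coefficients is positive; negative calls
mirror this.  "Remaining" sets aside the single extreme triggering
coefficient -- excluding *all* above-threshold coefficients would make
strong multi-dataset support self-defeating.  When both signs trigger, the
majority over all defined coefficients rules, with ties conservatively
uncalled.  Coefficients undefined because a gene is constant in a dataset
are excluded from majorities; correlation cannot orient an edge, so every
call emits both directions as optional interactions; self-interactions are
never called.  Thresholds compare inclusively.  `find_max_threshold` walks
the candidate grid (default: the distinct absolute coefficients in (0,1))
downwards and returns the largest threshold whose induced ABN satisfies the
constraints; calls only ever accumulate as the threshold drops, so the scan
can stop at the first satisfiable point.  If even the minimum fails, the
first violated constraint is named.

## Synthetic ground truth

The generator emulates the study data's shape: seven condition-specific
expression datasets (signal on/off combinations, weighted towards richer
combinations so most of the network stays expressed), ~20 samples each,
log-normal emission around High/Low modes one decade apart (log10 sd 0.2
by default) -- the bimodal log10 structure that 2-means discretisation
assumes.

**Wiring.**  Gene-gene wiring is acyclic with exactly one primary activator
per gene (signals root the first genes, earlier genes chain the rest);
extra budget adds repressors and second activators onto chain-terminal
genes, under two rules: a gene's regulators must descend from distinct
signals (so some culture condition silences the co-regulators and isolates
each edge) and total in-degree stays at two.  Multi-activator genes use
all-activator (AND) conditions -- at the high activity levels the generator
produces, AND preserves pairwise correlation where OR dilutes it; repressed
genes use the strict condition (any active repressor silences).

**Sampling.**  Each expression sample is an *attractor* state: for acyclic
wiring, evaluating genes in topological order is exactly the fixed point the
synchronous dynamics reach for fixed root activities, so samples are
end-states of trajectories rather than transient states (mid-trajectory
states carry essentially no usable pairwise correlation -- measured recall
zero under the calling rule).  Per-sample noise: stochastic signal
transduction (an ON signal reaches its direct target with probability 0.8),
basal root activity 0.3 (no lineage is ever fully silent, so no dataset's
coefficients degenerate to sign noise), and a per-gene state flip with
probability 0.05, which sets the correlation scale (direct positive pairs
~0.9, repressor pairs ~-0.7, two-step chains ~0.8).

**Identifiability ceiling.**  A gene with two regulators has pairwise |r|
at most 1/sqrt(2) to either one (1/sqrt(3) for three), while two-step chain
neighbours correlate at ~(1 - 2*flip)^2: no single threshold separates
multi-regulator direct edges from chain pairs.  The default planted
threshold is therefore 0.6, measured default recall is ~0.75-0.8 with
precision ~0.4-0.5, and that is a structural property of threshold-based
pairwise calling, not an implementation artefact -- in this methodology the
correlation screen only proposes candidates and the experimental
constraints carry model selection.  The `matching` structure (disjoint
regulator-target pairs, no indirect paths) removes the ceiling and is used
to demonstrate sharp recovery: precision and recall reach 1.0 as noise
drops.

**Observations and soundness.**  Constraints are read off the ground
truth's own simulated trajectories under resetting-, knockdown- and
forced-expression-shaped designs (stable/reached final states plus
never-reached probes with one gene flipped); held-out queries, half of them
probing perturbed targets, come with the ground truth's answer.  Since the
ground truth is by construction in the cABN synthesized from these
constraints, definitive predictions can never contradict it -- the
soundness chain asserts membership and accuracy 1.0 across 20 seeds.

## Study-system reconstruction

The shipped network (`fixtures/pluripotency.net`) is a *synthetic
reconstruction* of the published 16-component system (11 core TFs, MEK/ERK
and Tcf3, three inputs): definite interactions are the signal axes and
literature-direct regulations (LIF->Stat3 with effectors Tfcp2l1, Klf4,
Gbx2; CH -| Tcf3; PD -| MEK/ERK; Esrrb's definite activators Sall4, Nanog,
Tfcp2l1; Tcf3 repression of Tfcp2l1 and Esrrb; MEK/ERK repression of
Nanog), and 31 optional interactions form a correlation-style bidirectional
mesh among the core factors.  MEK/ERK and Tcf3 carry positive self-loops:
with activator-requiring update rules, a component that must stay High
until its inhibitor arrives needs a self-sustaining input; both start High
under FGF/Activin culture and are extinguished by PD/CH.  The six encoded
resetting behaviours (control never resets from all-off; EpiSCs reset and
stabilise in 2i+LIF; not in 2i alone; forced Tfcp2l1 rescues 2i; Nanog-null
EpiSCs fail in 2i+LIF but activate a six-gene module in LIF+CH) plus the
Sall4 no-faster comparative are satisfiable over the reconstruction, as is
the corpus including four reconstructed maintenance-era behaviours
(`fixtures/maintenance.exp`).  Quantities measured on this reconstruction
characterise the reconstruction; they are not re-derivations of the
published supplementary model's numbers.

## Asynchronous simulation

One gene updates per step; the updating gene is chosen uniformly at random
(no fairness guarantee) or by random-permutation rounds (weakly fair) --
the policy is configurable because fairness under asynchrony is an open
modelling question.  Synchronous fixed points are absorbing under any
order.  Batteries on a single model (typically the minimal model) are
scored by empirical reachability -- a reachability query counts positive if
the target is hit in at least one run (configurable threshold), an ordering
query by the majority of runs -- and validated in tests against exact
first-passage probabilities of the induced Markov chain and against
exhaustively enumerated interleavings.

## Numerical and design choices

* Seeds: every stochastic component takes an explicit seed; replays are
  bit-identical.  Derived seeds stay below 2^31.
* Solver defaults: 300 s per query, configurable; conflict budgets
  available; timeouts surface as indeterminate.
* Problem sizes: the soundness chain runs 6-gene/10-interaction ground
  truths with two allowed conditions per gene (a few hundred consistent
  models -- fully enumerable, so all-model queries are exact); the oracle
  cross-check uses <=4 components, <=6 optional interactions against
  exhaustive enumeration; the study-system reconstruction runs at its full
  size with the budget policy above.
* Ties and degenerate inputs: majority ties produce no call; constant genes
  are degenerate in discretisation and undefined in correlation; a
  component deletion drops experiments that clamp the deleted gene and
  projects it out of states elsewhere.

## Known limitations

* All-models refutations over very large consistent sets (>~10^4 models)
  can exceed any interactive budget with a pure-Python CDCL solver; such
  queries report indeterminate.  A compiled solver removes this limit, not
  the method.
* The correlation screen's recall/precision ceiling for multi-regulator
  genes is intrinsic to single-threshold pairwise calling (see above).
* The maintenance constraint corpus and the exact published network are
  reconstructions; counts measured on them (minimal-model size, deletion
  tolerance, classification splits) characterise the reconstruction.
* Synchronous determinism is an idealisation; the asynchronous module
  probes robustness to update order on single models only -- synthesis
  under asynchronous semantics is out of scope.
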