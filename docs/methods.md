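# Model and methods

## The crypt model

A human colon crypt is represented as a cylindrical lattice of
`circumference x height` sites (default 25 x 72), row 0 at the crypt
bottom and the top row at the lumen.  Each site is empty or holds one
cell; a cell's *normalized height* `h = row / (height - 1)` places it in
one of three compartments:

* **quiescent stem niche**, `h < niche_fraction` (default 0.1),
* **proliferating zone**, middle,
* **differentiated zone**, top `differentiated_fraction` (default 1/3).

Two positional gradients drive the dynamics.  The divide gradient falls
linearly from `divide_max` (0.25 per step) at the bottom to `divide_min`
(0) at the top; the die gradient rises from `die_min` (0.005) to
`die_max` (0.06).  One timestep corresponds to about 4 hours of human
time, so the default rates give proliferating cells residence times on
the scale of days and whole-crypt turnover on the scale of a week.

Each tick applies, in order:

1. **niche neutral replacement** — each stem cell occasionally
   (`niche_replace_prob` = 0.02 per step) divides symmetrically and
   replaces a lattice-neighbour stem cell.  This is the stem-niche
   neutral drift that produces monoclonal conversion;
2. **death draws** per occupied site;
3. **division draws** per surviving cell.  A daughter is placed just
   above or just below the parent, in the same or an adjacent column;
4. **compaction** of each column toward the bottom (gaps left by deaths
   close, insertions push the column up) and **shedding** of cells
   pushed past the top row.

Division flux exceeds death flux, so the lattice runs as a *full
conveyor*: it stays pinned near capacity, surplus cells stream out at the
lumen, and the observed total fluctuates narrowly around the homeostatic
target (1,750 cells for the default geometry; capacity 1,800).
Differentiated cells never divide.  Quiescent stem cells neither divide
nor die while the crypt is at size; when the total drops below
`release_fraction` (0.9) of the homeostatic target they awake, divide at
the full bottom-of-crypt rate to refill the crypt, and while awake are
as vulnerable as any dividing cell.  This release rule is what lets the
crypt recover between intermittent doses, and what makes sustained
high-intensity dosing genuinely lethal to the whole crypt.

### Phenotypes

Three phenotypes multiply the positional rates: normal (1.0, 1.0),
drug-sensitive cancer (divide x1.16, die x1.10) and relatively
drug-resistant cancer (x1.08, x1.05).  Two further mutant behaviours are
part of the model:

* **descent bias** (`mutant_descent_bias` = 0.7): mutant daughters are
  biased toward the crypt bottom, reflecting the failure of transformed
  cells to follow the upward migration cue.  A mutant clone can
  therefore anchor at the bottom of the proliferating zone and fill the
  crypt as an adenoma instead of being washed out by the conveyor.
  Without this, clones that have reached half the crypt still regress
  spontaneously in ~20% of runs, which contradicts the persistent
  adenoma the trial protocol assumes.
* **niche exclusion**: mutants cannot settle into stem-niche rows during
  compaction.  The niche is a protected compartment; if mutants could
  occupy it they would inherit its quiescent protection and produce rare
  never-curable stragglers.

### Drug effects

Both drugs act as multiplicative factors on the positional death
probability, clamped to [0, 1]:

* the **cytotoxic factor** (*lethality*, 5-FU-like) applies to dividing
  cells — the proliferating zone plus the niche while awake — weighted
  by the cell's divide multiplier, because an S-phase drug's exposure
  scales with division activity;
* the **apoptotic factor** (*intensity*, sulindac-like; the
  PTreatment/CptDieMax dial) applies to the differentiated top zone and
  shrinks the crypt from the lumen side.

Resistant cells additionally experience only `resistant_exposure` (0.75)
of the nominal cytotoxic exposure, modelling the slow-cycling /
persister state by which cancer cells escape S-phase-targeting drugs.
This is the load-bearing resistance mechanism.  We first implemented
resistance purely through the (1.08, 1.05) kinetic multipliers with
identical drug factors for all phenotypes, and measured the resulting
cure boundaries over several gradient calibrations: every kill and
regrowth force is linear in the same small multipliers, the faster
regrowth of the *sensitive* clone systematically offsets its extra
kill, and at the curative boundary the resistant clone came out equally
easy or *easier* to cure — inverting the clinically expected ordering.
A reduced-exposure persister state breaks that symmetry for a
principled reason and with it the expected structure emerges robustly:
the sensitive clone is cured 100% at lethality ~11–13 on the reduced
crypt, the resistant clone needs ~14–15 and longer, and a combination
with an apoptotic drug cures the resistant clone with roughly half the
accumulated cytotoxic dose of cytotoxic-alone.

### Calibration

For this class of models the biological anchors are fixed — the
phenotype multipliers, the 4-hour step, the 1,399-cell viability floor,
the treatment protocol — while lattice dimensions and gradient values
are free calibration choices.  Defaults
here were chosen once, by simulation, so that (i) the untreated default
crypt equilibrates within a few percent of a 1,750-cell homeostatic
target with the 1,399 floor at ~80% of it, (ii) turnover times are
biologically sensible, and (iii) clone establishment, adenoma formation,
cure and extinguishment all occur within the sweep's intensity range
(1–20).  `calibrate_gradients` exposes the same fitting loop
programmatically: a seeded random search over the gradient amplitudes
minimizing the weighted squared relative error of simulated compartment
means and variances against targets.

## Trial protocol

`run_trial` follows the simulated-clinical-trial design: initialize a
healthy crypt; at step 200 convert proliferating cells to the mutant
phenotype; let the clone grow untreated until it reaches 50% of the
crypt; then start therapy (both drugs of a combination simultaneously,
each subsequently on its own duration/interval cycle) and run to cure
(no cancer-lineage cells), crypt extinguishment, or a step cap (default
2,000 steps ≈ 333 days, comfortably above every observed cure time).
Replicates use independent seeds spawned from one master seed; because
the pre-therapy phase does not depend on the schedule, arms sharing a
master seed are paired on identical pre-therapy trajectories (common
random numbers), which sharpens every cross-arm comparison.

Aggregation over replicates: percent cure is computed over *evaluable*
replicates (those whose clone reached the trigger); time to cure and
accumulated dose (lethality x time-to-cure / interval, computed per
replicate and then averaged) over cured replicates; crypt size as the
treated-phase mean in percent of the untreated mean.  Toxicity of a
replicate means extinguishment, or — for apoptotic dosing — a dip below
the minimum viable crypt size (1,399 cells at full scale, the lowest
count measured in biopsies; scaled to 80% of target on other
geometries).

### Desk scale

The full-scale protocol (25x72 crypt, 50 replicates, single-cell
mutation) is the package default.  Tests and the worked examples use a
reduced geometry (20 x 30, target 585, floor 468) with
`TrialProtocol.desk()`: 20 replicates and 16 proliferating cells at the
crypt bottom converted at the mutation step.  Single-cell seeding is
faithful to the biology but at desk scale the mutant lineage almost
always drifts out before reaching the 50% trigger, so a clonal patch is
seeded instead; establishment then succeeds in ~95% of replicates and
the remainder are excluded as not evaluable.  Desk-scale results
reproduce the *structure* of the full-scale study (orderings of cure
rates, times, and accumulated doses across arms), not its printed
values, which depend on the original model's unpublished calibration and
HPC-scale sweeps.

## Sweeps and filtering

The single-drug sweep space is duration 1–48 (step 1) x interval 2–96
(even) x intensity 0.25–20.00 (step 0.25): 184,320 schedules, with
interval > duration enforced at execution (1,728 valid
duration/interval pairs).  The stated lower intensity bound of 1 would
give 77 grid values and a total inconsistent with the reported count;
80 values starting at 0.25 reproduce it exactly, so that is the
default, and both grids are configurable.  Curative filtering is
strict: 100% cure, no toxic or extinguished replicate.  Practicality
requires infusions of at most 2 steps (8 h) and whole-week intervals
(42, 84 steps).  Ranking is lexicographic: crypt size preserved, then
accumulated dose, then time to cure.  An optional robustness
post-filter drops curative schedules within one grid step of a
non-curative or toxic explored neighbour, since boundary schedules are
the ones most likely to fail under more replicates.

## Active learning

The combination space (184,320² schedules, 50 replicates each) is out
of reach of direct simulation, so toxicity is learned: label a seeded
uniform sample by simulation, train a probabilistic classifier —
per-drug duty-cycle and dose-pressure features appended to the raw
schedule vector, standardization, then a two-hidden-layer MLP
(logistic-regression fallback) —
predict over the whole space, label the batch with predicted P(toxic)
closest to 0.5, retrain, and stop when held-out sensitivity and
specificity both exceed 99%.  The held-out set is a fixed uniform
sample labeled once at the start rather than a split of the training
labels: uncertainty sampling concentrates training labels on the
decision boundary, and a split of them would measure boundary-case
accuracy — on which the loop never reaches 99% — rather than accuracy
over the schedule space, which is what the stopping rule is meant to
bound.  Predicted-nontoxic schedules are then re-simulated, so surrogate
false positives are self-correcting; false negatives merely remain
unexplored, which a large curative set tolerates.

Desk-scale runs of the loop use a synthetic 10,000-schedule space with a
deterministic smooth toxicity boundary (total drug pressure = intensity
x duty cycle summed over drugs): it preserves the geometry of the real
toxic region while labeling instantly.  Passing there shows the loop
machinery (batching, bookkeeping, stopping) works; it says nothing about
how hard the real simulated boundary is to learn.

## Numerical and reporting conventions

* Probabilities are clamped to [0, 1] after all multiplicative factors.
* Ties in compaction are broken by fixed (column, survivor-then-daughter)
  order via a stable sort; all randomness flows from one seeded
  generator per replicate, so identical (config, seed) gives bit-identical
  trajectories.
* Days are steps x 4/24, reported rounded half-up to 2 decimals.
* Reported accumulated doses average per-replicate doses; applying the
  dose formula to the mean time instead gives slightly different values,
  which is worth remembering when comparing printed tables.
* An extinguished crypt (0 cells) is a legal absorbing state.

## Known limitations

* The lattice is a cylinder with purely vertical mechanics; there is no
  explicit cell cycle, no pharmacokinetics, and drug effects switch on
  and off instantaneously with the schedule.
* Toxicity is crypt-local (extinguishment or the viability floor); no
  other organ systems are represented.
* The synthetic-data side of the trial arms (seeded clonal patches,
  reduced geometry) reproduces orderings, not magnitudes; absolute cure
  times and doses shift with geometry and calibration.
* The resistant phenotype's reduced cytotoxic exposure is a single
  effective parameter standing in for the whole biology of persistence;
  it is configurable and its value (0.75) was fixed during calibration,
  not fit to data.
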