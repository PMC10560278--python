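# Methods

This note documents the models, parameter choices, and numerical decisions
behind `bcinav`, and what the synthetic-data generators do and do not
emulate.

## Task and geometry

The robot occupies one cell of an `n_rows × n_cols` grid with
4-connectivity; the 9×1 and 20×20 configurations are the reference cases.
Each episode places the target uniformly over all cells and the robot
uniformly over the cells at Manhattan distance ≥ 2 from it, with no maximum
distance. (Only the minimum-distance constraint is fixed by the paradigm;
the uniform start distribution is our choice, and the start marginal is
checked by test.) Because moves are 4-connected, every movement changes the
distance to any fixed cell by exactly ±1, so the four movement classes —
TT, TR, FA, SO — partition all adjacent moves; identifications are CTI on
the target and FTI elsewhere. Coordinates are 0-based internally and
1-based in all user-facing output.

## Observation model

Classifier feedback is modelled by column-stochastic likelihood matrices
`A[observation, state] = P(O | S)` — 4×4 for movements, 2×2 for
identifications. Two matrices per kind are carried by a
`ParticipantProfile`:

* the **sampler**, standing in for the subject's true test-set behaviour
  (drawing an observation from the true class's column replaces retrieving
  and classifying a held-out EEG trial);
* the **assumed** matrix the robot reasons with (in the real pipeline a
  leave-one-out estimate from training data).

The two coincide by default (`mismatch = 0`); a positive `mismatch` blends
the assumed matrix towards an independent draw to emulate estimate error.

Indexing convention: only `P(O | S)` enters the update, so the matrix is
stored observation-by-state and the per-observation likelihoods over states
are a row of `A` (a soft observation — a probability vector over classes —
is accepted and forms the weighted average of rows; this hook is off by
default and carries no calibration machinery).

**Likelihood floor.** Contingency tables are column-normalised, floored at
`ε = 1e-6`, and re-normalised. Without the floor, a single unlucky
misclassification whose likelihood is exactly zero under the true target
would zero that cell's posterior permanently. The floor is configurable;
pure identity matrices (used in the perfect-feedback limits) are
constructible without flooring.

## Bayesian strategy

The posterior over target cells starts uniform and is updated after every
observed action: each cell's mass is multiplied by the likelihood of the
observation under the *counterfactual* class the action would have had if
that cell were the target, divided by the marginal `P(O)` (row sum over the
matrix total), then renormalised over the grid. The marginal divides every
cell equally, so it cancels under normalisation; it is computed anyway for
faithfulness to the model, and a test confirms the cancellation
algebraically. A brute-force per-cell oracle pins the vectorised update to
1e-12 on random small instances.

**Identification thresholds.** The decision rule after each movement update
uses two thresholds derived from the stringency `s`:

* lower (with a TR output): `P(T_c) > s`;
* upper (without one): `P(T_c) > (s + 0.1) / (s + 0.2)`.

At `s = 0.1` these reproduce the two published anchors — "more than a 10%
chance" with TR, and "more than twice as likely than all other loci
combined" (2/3) without — and the upper formula is exactly the threshold
printed for the binary-classification variant. The exact functional form at
other stringencies is our reconstruction; inequalities are strict. The rule
is monotone: raising `s` can only withdraw an identification. The check
runs only after movement updates; after a deselection the next action is
always a movement.

**Action selection.** The robot steps along a shortest path towards the
argmax cell, ties broken uniformly at random (both among tied argmax cells
and among tied first steps). When the argmax is the robot's own cell but
the thresholds are unmet, it steps towards the most probable *other* cell:
staying put would deadlock and gather no evidence, and the move is the
cheapest way to discriminate the current cell from the runner-up.

**Variants.** `no_tic` drops the TI layer (the first identification ends
the run); `binary` collapses movement feedback to {correct = TT+TR,
error = FA+SO}: the sampler still draws a 4-way output which is then
group-mapped (equivalent to sampling the collapsed table given the true
class), the assumed matrix is the collapsed 2×2, and only the upper
threshold applies since no TR output exists.

## Baselines

**React** trusts the latest classification completely: TR → identify;
FA/SO → move back, undoing the error; TT → uniform step excluding the
previous cell, the exclusion lasting one action only. At a dead end whose
only neighbour is the excluded cell, the exclusion is waived (the robot
must move). After an FTI-undone identification the stale TR output is
discarded and all neighbours are eligible; the one-step `previous` memory
is kept.

**Random** identifies with probability `1/(n·m)` per action, else moves to
a uniform random neighbour, and ends at its first identification with no TI
layer. Its policy is the same at every step *including the first*, so a run
can end at step 0 with a (necessarily wrong) identification — this
convention reproduces the published chance baselines on both grids, whereas
forcing an initial movement overestimates PTCI on the small grid by about
one percentage point. React and the Bayesian strategy instead open with a
uniform-random movement, since both need an observation before their rules
apply.

## Episode loop and metrics

Runs terminate when an identification is answered CTI (or immediately for
`no_tic`/Random). `movement_steps` counts movement actions only;
identifications and undone identifications are free. A step cap of
`50·n·m` movement actions guards against non-termination under adversarial
matrices; capped runs are recorded and scored incorrect (none occur under
the study conditions).

PTCI = 100 × (correct runs / runs). MNS = mean over correct runs of
`movement_steps / initial_distance`; participants average over their own
correct runs first, headline values average those means across participants
(a participant with no correct run contributes no MNS value — missing, not
zero). Per-run normalised steps are also retained for pooled
(violin-style) summaries, which aggregate differently from the
participant-mean table. Sweeps derive one independent child stream per
(condition, participant) from the global seed, so any cell is reproducible
in isolation.

## SWLDA layer

Epoch features: zero-phase 4th-order Butterworth band-pass at the native
500 Hz (1–10 Hz for stage 1 and TI, 1–32 Hz for stage 2), polyphase
resampling to 64 Hz, per-channel baseline correction on [−200, 0) ms, and
the half-open [200, 700) ms window concatenated across the 8 channels →
8 × 32 = 256 features. The half-open endpoint convention makes the count
deterministic. Filtering epoch-wise leaves edge transients from the 1 Hz
corner inside short epochs; the filter-response test therefore checks
steady-state attenuation on a long epoch, and the synthetic templates are
near-zero at the epoch edges where the transients live.

Stepwise selection regresses ±1-coded labels on features with
forward-entry (partial-F p < `entry_p`) and backward-removal (coefficient
t-test p > `removal_p`), implemented on Gram matrices so each candidate
sweep is one vectorised solve; the incremental p-values are cross-checked
against statsmodels OLS in a test. Defaults `entry_p = 0.05`,
`removal_p = 0.10`, `max_features = 60` are conventional ERP practice; all
are configurable, and the test suite uses smaller feature budgets with
correspondingly small epoch counts. Four-way movement classification is a
two-stage tree (correct-vs-error, then TT-vs-TR or FA-vs-SO); stage-2
models train only on epochs whose true class belongs to their branch.
Leave-one-out likelihood estimation precomputes features once and refits
the selection per fold.

A known LOO property worth stating: when features carry no information
about the labels *and* the stepwise selection admits no feature, the
intercept-only model predicts the training majority, and holding out an
epoch makes its own class the minority — LOO accuracy collapses to ~0
rather than chance on balanced classes. Chance-level diagonals are
therefore asserted on zero-SNR (pure-noise) epochs, where spurious feature
entries decouple predictions from the held-out label.

## Synthetic ERP generator

Templates are sums of Gaussian bumps with a fixed fronto-central scalp
weighting, one waveform per class, emulating the qualitative grand-average
structure: erroneous actions (FA, SO, FTI) evoke larger deflections than
correct ones, TR exceeds TT, SO exceeds FA, with class-specific latencies
(0.30/0.45/0.33/0.50 s positive peaks) so classes are separable at high
SNR. Trials are `template × (1 + jitter)` plus 1/f coloured noise;
defaults: amplitude jitter s.d. 0.25, noise exponent 1, noise scale 3
(µV-like units, comparable to the 3–7 unit template peaks — i.e.
realistic single-trial SNR). A stratified 85/15 train/test split utility
matches the study workflow, and `paradigm_class_counts` reproduces the
class imbalance induced by the scripted acquisition paradigm (70/20/10
off-target and 67/33 on-target action probabilities on the 9-cell
display).

What the generator does **not** emulate: real electrode covariance and
volume conduction, latency jitter and non-Gaussian component shapes,
artefacts (blinks, EMG), non-stationarity across blocks, or
between-subject topography differences. Passing tests therefore show the
pipeline's correctness and its behaviour under controlled SNR, not
expected classification accuracy on real EEG; real 4-way ErrP accuracies
are far below the high-SNR synthetic regime, which is why simulation
results with synthetic profiles (e.g. 70% movement accuracy) exceed the
EEG-derived figures.

## Problem sizes

The reference benchmark (acceptance script) uses the study's full Random
configuration: 8 participants × 1000 runs per grid. Test-suite simulations
use 100–2000 runs per condition and the SWLDA tests use 30 epochs per class
with an 8-feature budget — sizes chosen to make the statistical assertions
(binomial/monotonicity bands, LOO diagonals) well-powered while keeping the
suite quick to run.

## Known limitations

* Thresholds other than the two printed anchors are a reconstruction (see
  above); alternative monotone interpolations would also match the anchors.
* The binary variant's assumed 2×2 matrix collapses the 4×4 likelihood
  with equal within-group weights when only matrices (not counts) are
  available; collapsing raw counts is exact and preferred when they exist.
* No online learning of `A`, non-uniform target priors are accepted as an
  initial posterior but not learned, and no artefact rejection or
  streaming classification is provided.
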