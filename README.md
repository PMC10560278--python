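# bcinav

Bayesian target inference for EEG-guided robot navigation.

A robot moves on a grid towards a target that only the human observer knows.
The only feedback it receives is a noisy single-trial classification of the
observer's error-related brain response (ErrP) to each action: a four-way
label for movements — *TT* (towards target), *TR* (target reached), *FA*
(further away), *SO* (stepped off) — and a binary label for target
identifications — *CTI* / *FTI* (correct / false target identification).
`bcinav` implements the full inference-and-simulation stack for this
problem: the grid world, the confusion-matrix observation model, a Bayesian
navigation strategy with an adjustable evidence threshold, React/Random
baselines, the SWLDA ERP-classification layer with a synthetic-ERP
generator, and the evaluation metrics. It is aimed at BCI and
human-robot-interaction researchers who want to study implicit,
cognitive-probing control loops in simulation.

## The model

The robot maintains a posterior $P(T_{i,j}^t)$ that cell $(i,j)$ is the
target, initialised uniform at $1/(n\times m)$. After each action $U_t$ the
classifier output $\mathbf{O_t}$ updates every cell by Bayes' rule

$$P(T_{i,j}^{t+1}) \propto P_{\mathbf A}(\mathbf{O_t}\mid T_{i,j})\,P(T_{i,j}^t),$$

where the likelihood is read from a column-stochastic matrix
$\mathbf A(i,j) = P(\mathcal O(i)\mid\mathcal S(j))$ — the robot's model of
its classifier's reliability, estimated by leave-one-out cross-validation on
training trials — at the *counterfactual* class the action would have had if
$(i,j)$ were the target. The robot then steps along a shortest path to the
most probable cell. It identifies its current cell $c$ when either

* the classifier reported **TR** and $P(T_c) > s$, or
* it reported anything else and $P(T_c) > \dfrac{s+0.1}{s+0.2}$,

with the *stringency* $s \in [0.1, 0.9]$ governing a speed–accuracy
trade-off. A false identification (TI classifier says FTI) deselects the
cell by the same Bayes update with the 2×2 identification matrix, and the
run continues until an identification is answered CTI.

Performance is measured by **PTCI** (percentage of targets correctly
identified) and **MNS** (mean normalised steps: movement actions divided by
the initial shortest-path distance, over correct runs; 1.0 is a perfect
direct path).

## Worked example

```python
import numpy as np
from bcinav import Grid, uniform_diagonal_profile, run_many, ptci, mns

profile = uniform_diagonal_profile(0.7, 0.8, id="p1")  # 70% movement, 80% TI accuracy
grid = Grid(9, 1)
print("stringency  PTCI(%)   MNS")
for i, s in enumerate((0.1, 0.5, 0.9)):
    recs = run_many("bayes", profile, grid, 1000,
                    np.random.default_rng(100 + i), stringency=s)
    print(f"       {s}    {ptci(recs):5.1f}  {mns(recs):.2f}")
```

prints

```
stringency  PTCI(%)   MNS
       0.1     89.8  1.99
       0.5     94.1  2.17
       0.9     99.3  2.86
```

Raising the stringency makes the robot demand more posterior mass before
naming a target: accuracy (PTCI) rises towards 100% while the path cost
(MNS) grows — the speed–accuracy trade-off in miniature. The same loop runs
with `"react"` (trust the last classification only) or `"random"` (identify
with probability $1/(n\times m)$) to reproduce the baselines, and
`bcinav.simulate.run_sweep` evaluates whole grids of
participants × stringencies × variants in one call.

The command line mirrors the library:

```sh
bcinav synth --what profiles --participants 8 --out profiles/
bcinav simulate --strategy bayes --grid 9x1 --runs 1000 --seed 1 --out results/
bcinav synth --what epochs --out synth/          # synthetic ERP epochs
bcinav train synth/movement/manifest.csv --ti-manifest synth/ti/manifest.csv
```

`simulate` writes one CSV row per run, an aggregate CSV (mean ± s.d. of
PTCI and MNS across participants per condition), and a JSON manifest that
re-runs to identical output under the same seed.

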