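"""Bayesian target-inference navigation strategy.

The robot maintains a posterior P(T_{i,j}) over which grid cell is the
target, starting uniform at 1/(n·m).  After every action it receives a noisy
classifier output O_t, and updates each cell's mass by Bayes' rule:

    P(T_{i,j} | O_t)  ∝  P_A(O_t | T_{i,j}) · P(T_{i,j}),

where the likelihood P_A(O_t | T_{i,j}) is read from the likelihood matrix
``A`` at the *counterfactual* class the action would have had if cell (i, j)
were the target.  A single movement therefore reweights every cell at once:
cells the robot moved towards gain mass when the classifier reports TT, and
so on.  The marginal P(O_t) divides every cell equally and cancels under the
final normalisation.

Identification is governed by a *stringency* parameter s ∈ [0.1, 0.9] with
two evidence thresholds checked after each movement update:

* classifier said TR and P(T_c) > s               (lower threshold), or
* classifier said anything else and
  P(T_c) > (s + 0.1) / (s + 0.2)                  (upper threshold).

At s = 0.1 these reduce to "more than a 10% chance" with a TR output, and
"more than twice as likely as all other cells combined" (2/3) without one.
A false identification (TI classifier says FTI) deselects the cell via the
same Bayes update with the 2x2 identification likelihood matrix, and the run
continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .actions import Action, Identify, Move
from .feedback import KindError, LikelihoodMatrix, Observation, observation_marginal
from .gridworld import (
    EpisodeState,
    Grid,
    MovementClass,
    MovementEvent,
    Position,
    TIClass,
    manhattan_distance,
    shortest_path_first_step,
    true_movement_class,
)

__all__ = [
    "PosteriorField",
    "StringencyConfig",
    "counterfactual_state",
    "counterfactual_classes",
    "bayes_update_movement",
    "bayes_update_ti",
    "decide_identification",
    "next_action_bayes",
    "BayesStrategy",
]


@dataclass
class PosteriorField:
    """Posterior probability of each cell being the target."""

    grid: Grid
    probabilities: np.ndarray  # flat, row-major, sums to 1

    @classmethod
    def uniform(cls, grid: Grid) -> "PosteriorField":
        return cls(grid, np.full(grid.n_cells, 1.0 / grid.n_cells))

    def probability_at(self, p: Position) -> float:
        return float(self.probabilities[self.grid.cell_index(p)])

    def as_array(self) -> np.ndarray:
        return self.probabilities.reshape(self.grid.n_rows, self.grid.n_cols)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.as_array(), delimiter=",")

    def check_normalised(self, atol: float = 1e-9) -> None:
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > atol:
            raise AssertionError(f"posterior sums to {total}, not 1")


@dataclass(frozen=True)
class StringencyConfig:
    """Evidence thresholds derived from a single stringency value."""

    stringency: float

    def __post_init__(self) -> None:
        if not 0.1 - 1e-12 <= self.stringency <= 0.9 + 1e-12:
            raise ValueError(f"stringency must lie in [0.1, 0.9], got {self.stringency}")

    @property
    def lower_threshold(self) -> float:
        return self.stringency

    @property
    def upper_threshold(self) -> float:
        return (self.stringency + 0.1) / (self.stringency + 0.2)


def counterfactual_state(ev: MovementEvent, hypothesized_target: Position) -> MovementClass:
    """Class the move *would* have had if ``hypothesized_target`` were the target."""
    return true_movement_class(ev, hypothesized_target)


def counterfactual_classes(grid: Grid, ev: MovementEvent) -> np.ndarray:
    """Vector of counterfactual movement classes, one per cell (flat order).

    For each cell t: TR if the destination is t, SO if the origin is t,
    TT if the move shortened the distance to t, FA otherwise.
    """
    rows, cols = grid.index_arrays()
    d0 = np.abs(rows - ev.origin.row) + np.abs(cols - ev.origin.col)
    d1 = np.abs(rows - ev.destination.row) + np.abs(cols - ev.destination.col)
    cls = np.where(d1 < d0, int(MovementClass.TT), int(MovementClass.FA))
    cls[grid.cell_index(ev.origin)] = int(MovementClass.SO)
    cls[grid.cell_index(ev.destination)] = int(MovementClass.TR)
    return cls


def _movement_state_indices(grid: Grid, ev: MovementEvent, binary: bool) -> np.ndarray:
    cls = counterfactual_classes(grid, ev)
    if binary:
        # correct = {TT, TR} -> 0, error = {FA, SO} -> 1
        return (cls >= int(MovementClass.FA)).astype(np.intp)
    return cls


def _apply_bayes(
    p: PosteriorField, per_state: np.ndarray, states: np.ndarray, marginal: float
) -> PosteriorField:
    # Eq.-style per-cell reweighting; the marginal divides all cells equally
    # and cancels under normalisation (kept for faithfulness to the model).
    unnorm = per_state[states] * p.probabilities / marginal
    total = unnorm.sum()
    if total <= 0:
        raise ZeroDivisionError("posterior collapsed to zero mass; likelihoods too degenerate")
    return PosteriorField(p.grid, unnorm / total)


def bayes_update_movement(
    p: PosteriorField,
    ev: MovementEvent,
    o: Union[Observation, np.ndarray],
    A: LikelihoodMatrix,
) -> PosteriorField:
    """Posterior update after one movement and its classifier output.

    ``A`` may be the 4x4 movement matrix or the collapsed 2x2 correct/error
    matrix (the binary-classification variant); ``o`` may be one-hot or a
    soft probability vector over observation classes.
    """
    if A.kind == "movement":
        binary = False
    elif A.kind == "movement_binary":
        binary = True
    else:
        raise KindError(f"movement update requires a movement likelihood, got {A.kind!r}")
    per_state = A.state_likelihoods(o)
    if isinstance(o, Observation):
        marginal = observation_marginal(A, o)
    else:
        marginal = float(per_state.sum() / A.entries.sum())
    states = _movement_state_indices(p.grid, ev, binary)
    return _apply_bayes(p, per_state, states, marginal)


def bayes_update_ti(
    p: PosteriorField,
    loc: Position,
    o: Union[Observation, np.ndarray],
    A: LikelihoodMatrix,
) -> PosteriorField:
    """Posterior update after a target identification at ``loc``.

    Counterfactually the identification is CTI only if the identified cell is
    the target, FTI for every other cell.
    """
    if A.kind != "ti":
        raise KindError(f"TI update requires a 2x2 'ti' likelihood, got {A.kind!r}")
    per_state = A.state_likelihoods(o)
    if isinstance(o, Observation):
        marginal = observation_marginal(A, o)
    else:
        marginal = float(per_state.sum() / A.entries.sum())
    states = np.full(p.grid.n_cells, int(TIClass.FTI), dtype=np.intp)
    states[p.grid.cell_index(loc)] = int(TIClass.CTI)
    return _apply_bayes(p, per_state, states, marginal)


def decide_identification(
    p: PosteriorField,
    current: Position,
    last_obs: Observation,
    cfg: StringencyConfig,
    binary: bool = False,
) -> bool:
    """Whether to identify the current cell, given the latest movement output.

    With 4-way movement classification a TR output lowers the evidence bar to
    the stringency itself; otherwise (and always in the binary variant, which
    has no TR output) the upper threshold applies.  Inequalities are strict.
    """
    if last_obs.kind == "ti":
        raise KindError("identification decision requires a movement observation")
    p_c = p.probability_at(current)
    if not binary and last_obs.kind == "movement" and last_obs.index == int(MovementClass.TR):
        return p_c > cfg.lower_threshold
    return p_c > cfg.upper_threshold


def _argmax_cell(
    p: PosteriorField, rng: np.random.Generator, exclude: Optional[Position] = None
) -> Position:
    probs = p.probabilities
    if exclude is not None:
        probs = probs.copy()
        probs[p.grid.cell_index(exclude)] = -np.inf
    best = probs.max()
    tied = np.nonzero(probs >= best - 1e-12)[0]
    return p.grid.position(int(tied[int(rng.integers(len(tied)))]))


def next_action_bayes(
    p: PosteriorField,
    s: EpisodeState,
    last_obs: Optional[Observation],
    cfg: StringencyConfig,
    rng: np.random.Generator,
    binary: bool = False,
) -> Action:
    """Identify if a threshold is met, else step toward the most probable cell.

    Ties for the highest probability are broken uniformly at random.  When the
    most probable cell is the robot's own cell but the evidence thresholds are
    unmet, the robot steps toward the most probable *other* cell (staying put
    would gather no new evidence).  The identification check only applies when
    the last action was a movement.
    """
    if last_obs is not None and decide_identification(p, s.robot, last_obs, cfg, binary=binary):
        return Identify(s.robot)
    goal = _argmax_cell(p, rng)
    if goal == s.robot:
        goal = _argmax_cell(p, rng, exclude=s.robot)
    return Move(shortest_path_first_step(s.grid, s.robot, goal, rng))


@dataclass
class BayesStrategy:
    """Stateful wrapper implementing the strategy protocol.

    ``movement_A`` is the matrix the robot *assumes* for movement
    classifications (4x4, or 2x2 for the binary-classification variant);
    ``ti_A`` the assumed 2x2 identification matrix.  An optional non-uniform
    ``initial_posterior`` is accepted (e.g. learned target preferences) but
    defaults to uniform.
    """

    movement_A: LikelihoodMatrix
    ti_A: LikelihoodMatrix
    stringency: float = 0.1
    initial_posterior: Optional[np.ndarray] = None
    name: str = "bayes"

    posterior: PosteriorField = field(init=False, repr=False, default=None)
    _last_obs: Optional[Observation] = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if self.movement_A.kind not in ("movement", "movement_binary"):
            raise KindError("movement_A must be a movement likelihood matrix")
        if self.ti_A.kind != "ti":
            raise KindError("ti_A must be a 2x2 'ti' likelihood matrix")
        self.config = StringencyConfig(self.stringency)

    @property
    def binary(self) -> bool:
        return self.movement_A.kind == "movement_binary"

    def reset(self, state: EpisodeState, rng: np.random.Generator) -> None:
        if self.initial_posterior is not None:
            probs = np.asarray(self.initial_posterior, dtype=float).ravel()
            if probs.size != state.grid.n_cells or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("initial posterior must be a normalised field over the grid")
            self.posterior = PosteriorField(state.grid, probs.copy())
        else:
            self.posterior = PosteriorField.uniform(state.grid)
        self._last_obs = None

    def initial_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        from .gridworld import neighbours

        nb = neighbours(state.grid, state.robot)
        return Move(nb[int(rng.integers(len(nb)))])

    def observe_movement(self, ev, obs, state) -> None:
        self.posterior = bayes_update_movement(self.posterior, ev, obs, self.movement_A)
        self._last_obs = obs

    def observe_ti_false(self, position, state) -> None:
        o = Observation(int(TIClass.FTI), "ti")
        self.posterior = bayes_update_ti(self.posterior, position, o, self.ti_A)
        # the next identification check must wait for a fresh movement output
        self._last_obs = None

    def next_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        return next_action_bayes(
            self.posterior, state, self._last_obs, self.config, rng, binary=self.binary
        )
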