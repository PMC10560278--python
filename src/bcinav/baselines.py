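"""React and Random baseline navigation strategies.

*React* puts full trust in the most recent classifier output: a TR output
triggers identification of the current cell, an error output (FA or SO) sends
the robot straight back to its previous cell, and a TT output rules the
previous cell out of the next uniform-random step.  Exclusions last a single
action.  There is no memory beyond one step and no probabilistic model.

*Random* is the chance baseline: each action identifies the current cell with
probability 1/(n·m) and otherwise moves to a uniformly random neighbour.  It
uses no classifier feedback at all and its runs end at the first
identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .actions import Action, Identify, Move
from .feedback import Observation
from .gridworld import EpisodeState, MovementClass, MovementEvent, Position, neighbours

__all__ = ["ReactStrategy", "RandomStrategy", "react_next_action", "random_next_action"]


@dataclass
class ReactState:
    """One-step memory of the React strategy."""

    previous: Optional[Position] = None
    last_obs: Optional[Observation] = None


def react_next_action(
    s: EpisodeState, rs: ReactState, rng: np.random.Generator
) -> Action:
    """Next React action from the most recent movement classification.

    With no usable output (start of run, or just after an undone
    identification — exclusions last one action only, and the identification
    was an action) all neighbours are eligible.
    """
    obs = rs.last_obs
    if obs is not None:
        if obs.index == int(MovementClass.TR):
            return Identify(s.robot)
        if obs.index in (int(MovementClass.FA), int(MovementClass.SO)):
            if rs.previous is None:
                raise RuntimeError("error-undo requested before any movement")
            return Move(rs.previous)
    nb = neighbours(s.grid, s.robot)
    if obs is not None and obs.index == int(MovementClass.TT):
        eligible = [q for q in nb if q != rs.previous]
        # at a dead end the sole neighbour may be the previous cell; the
        # exclusion is waived because the robot must move somewhere
        if eligible:
            nb = eligible
    return Move(nb[int(rng.integers(len(nb)))])


def random_next_action(
    s: EpisodeState, rng: np.random.Generator
) -> Action:
    """Identify with probability 1/(n·m), else a uniform neighbour move."""
    if rng.random() < 1.0 / s.grid.n_cells:
        return Identify(s.robot)
    nb = neighbours(s.grid, s.robot)
    return Move(nb[int(rng.integers(len(nb)))])


@dataclass
class ReactStrategy:
    name: str = "react"
    _state: ReactState = field(default_factory=ReactState, repr=False)

    def reset(self, state: EpisodeState, rng: np.random.Generator) -> None:
        self._state = ReactState()

    def initial_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        nb = neighbours(state.grid, state.robot)
        return Move(nb[int(rng.integers(len(nb)))])

    def observe_movement(self, ev: MovementEvent, obs, state) -> None:
        if obs is not None and obs.kind != "movement":
            raise ValueError("React requires 4-way movement observations")
        self._state.previous = ev.origin
        self._state.last_obs = obs

    def observe_ti_false(self, position: Position, state) -> None:
        # identification undone; one-step memory of `previous` is kept, but
        # the TR output that triggered the identification is now stale
        self._state.last_obs = None

    def next_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        return react_next_action(state, self._state, rng)


@dataclass
class RandomStrategy:
    name: str = "random"
    uses_feedback: bool = False

    def reset(self, state: EpisodeState, rng: np.random.Generator) -> None:
        pass

    def initial_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        # the Random policy is the same at every step, including the first:
        # it may identify immediately (necessarily wrongly, given starts are
        # at distance >= 2)
        return random_next_action(state, rng)

    def observe_movement(self, ev, obs, state) -> None:
        pass

    def observe_ti_false(self, position, state) -> None:
        raise RuntimeError("Random strategy runs end at the first identification")

    def next_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        return random_next_action(state, rng)
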