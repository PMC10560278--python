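"""Action types and the navigation-strategy protocol shared by all strategies."""

from __future__ import annotations

from typing import NamedTuple, Optional, Protocol, Union, runtime_checkable

import numpy as np

from .feedback import Observation
from .gridworld import EpisodeState, MovementEvent, Position


class Identify(NamedTuple):
    """Identify ``position`` (the robot's current cell) as the target."""

    position: Position


class Move(NamedTuple):
    """Move to the adjacent cell ``destination``."""

    destination: Position


Action = Union[Identify, Move]


@runtime_checkable
class Strategy(Protocol):
    """A navigation policy driven by (possibly absent) classifier feedback."""

    name: str

    def reset(self, state: EpisodeState, rng: np.random.Generator) -> None:
        """Prepare for a fresh episode."""

    def initial_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        """The first action of a run."""

    def observe_movement(
        self, ev: MovementEvent, obs: Optional[Observation], state: EpisodeState
    ) -> None:
        """Consume the classifier output for a completed movement."""

    def observe_ti_false(self, position: Position, state: EpisodeState) -> None:
        """An identification at ``position`` was judged false; deselect it."""

    def next_action(self, state: EpisodeState, rng: np.random.Generator) -> Action:
        """Propose the next action given everything observed so far."""
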