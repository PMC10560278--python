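"""Grid geometry, action semantics, and ground-truth labelling.

The virtual robot lives on a rectangular grid of ``n_rows x n_cols`` cells
with 4-connectivity (no diagonal moves).  Every movement action changes the
Manhattan distance to the target by exactly +/-1, so each adjacent move falls
into exactly one of four classes:

* ``TT`` — towards the target, without reaching it,
* ``TR`` — target reached (destination is the target),
* ``FA`` — further away, starting from an off-target cell,
* ``SO`` — stepped off the target cell.

Target-identification actions are labelled ``CTI`` (correct target
identification) when performed on the target cell and ``FTI`` (false target
identification) otherwise.

Coordinates are 0-based internally; user-facing formatting is 1-based
(:meth:`Position.display`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "Grid",
    "Position",
    "MovementEvent",
    "MovementClass",
    "TIClass",
    "EpisodeState",
    "manhattan_distance",
    "neighbours",
    "true_movement_class",
    "true_ti_class",
    "init_episode",
    "shortest_path_first_step",
]


class MovementClass(IntEnum):
    """Four-way movement labelling; the integer value is the fixed class index."""

    TT = 0
    TR = 1
    FA = 2
    SO = 3


class TIClass(IntEnum):
    """Binary target-identification labelling."""

    CTI = 0
    FTI = 1


class Position(NamedTuple):
    row: int
    col: int

    def display(self) -> tuple[int, int]:
        """1-based coordinates for user-facing output."""
        return (self.row + 1, self.col + 1)


@dataclass(frozen=True)
class Grid:
    """A rectangular grid of at least two cells."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 2:
            raise ValueError(
                f"grid must have at least 2 cells, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, p: Position) -> bool:
        return 0 <= p.row < self.n_rows and 0 <= p.col < self.n_cols

    def require(self, p: Position) -> None:
        if not self.contains(p):
            raise InvalidPositionError(f"position {tuple(p)} outside {self.n_rows}x{self.n_cols} grid")

    def cell_index(self, p: Position) -> int:
        """Row-major flat index of a cell."""
        return p.row * self.n_cols + p.col

    def position(self, index: int) -> Position:
        return Position(index // self.n_cols, index % self.n_cols)

    def all_positions(self) -> list[Position]:
        return [Position(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    # row/col index arrays for vectorised per-cell distance computations
    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        rows = np.repeat(np.arange(self.n_rows), self.n_cols)
        cols = np.tile(np.arange(self.n_cols), self.n_rows)
        return rows, cols


class InvalidPositionError(ValueError):
    pass


class InvalidMoveError(ValueError):
    pass


class MovementEvent(NamedTuple):
    """A single discrete move between 4-neighbour adjacent cells."""

    origin: Position
    destination: Position


@dataclass
class EpisodeState:
    """Mutable state of one simulated run."""

    grid: Grid
    target: Position
    robot: Position
    previous: Optional[Position] = None
    t: int = 0
    initial_distance: int = 0
    pending_identification: bool = field(default=False)


def manhattan_distance(a: Position, b: Position) -> int:
    """Minimum number of 4-connected steps between two cells."""
    return abs(a.row - b.row) + abs(a.col - b.col)


_STEPS = (Position(1, 0), Position(-1, 0), Position(0, 1), Position(0, -1))


def neighbours(grid: Grid, p: Position) -> list[Position]:
    """In-grid 4-neighbours of ``p``, in fixed (down, up, right, left) order."""
    grid.require(p)
    out = []
    for d in _STEPS:
        q = Position(p.row + d.row, p.col + d.col)
        if grid.contains(q):
            out.append(q)
    return out


def true_movement_class(ev: MovementEvent, target: Position) -> MovementClass:
    """Ground-truth class of an adjacent move given the actual target.

    Exactly one branch applies: a 4-connected move changes the Manhattan
    distance to any fixed cell by exactly +/-1, so "same distance" moves
    cannot occur.
    """
    if manhattan_distance(ev.origin, ev.destination) != 1:
        raise InvalidMoveError(f"move {ev.origin}->{ev.destination} is not 4-adjacent")
    if ev.destination == target:
        return MovementClass.TR
    if ev.origin == target:
        return MovementClass.SO
    d0 = manhattan_distance(ev.origin, target)
    d1 = manhattan_distance(ev.destination, target)
    return MovementClass.TT if d1 < d0 else MovementClass.FA


def true_ti_class(p: Position, target: Position) -> TIClass:
    """CTI when the identified cell is the target, FTI otherwise."""
    return TIClass.CTI if p == target else TIClass.FTI


def init_episode(grid: Grid, rng: np.random.Generator) -> EpisodeState:
    """Draw a fresh episode: target uniform over all cells, start uniform over
    cells at Manhattan distance >= 2 from the target (no maximum distance).
    """
    cells = grid.all_positions()
    target = cells[int(rng.integers(len(cells)))]
    eligible = [p for p in cells if manhattan_distance(p, target) >= 2]
    if not eligible:
        raise ValueError(
            f"grid {grid.n_rows}x{grid.n_cols} has no start cell at distance >= 2"
        )
    start = eligible[int(rng.integers(len(eligible)))]
    return EpisodeState(
        grid=grid,
        target=target,
        robot=start,
        initial_distance=manhattan_distance(start, target),
    )


def shortest_path_first_step(
    grid: Grid, origin: Position, to: Position, rng: np.random.Generator
) -> Position:
    """First step of a shortest path from ``origin`` to ``to``.

    When both a row-wise and a column-wise step shorten the path, one is
    chosen uniformly at random.
    """
    if origin == to:
        raise InvalidMoveError("already at destination; no move to make")
    grid.require(origin)
    grid.require(to)
    d = manhattan_distance(origin, to)
    options = [q for q in neighbours(grid, origin) if manhattan_distance(q, to) == d - 1]
    return options[int(rng.integers(len(options)))]
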