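"""Episode loop, PTCI/MNS metrics, and multi-participant sweeps.

A *run* starts with the target placed uniformly at random and the robot at a
uniform random cell at least 2 steps away.  The strategy then alternates
movement actions (each labelled with its ground-truth class and answered by a
noisy classifier output sampled from the participant's confusion behaviour)
and, when its rule fires, target-identification actions.  With the TI layer
on, a false identification is detected with the participant's TI accuracy
and undone; the run ends when an identification is answered CTI.  Without TI
classification (``no_tic``) the run ends at the first identification.  The
Random baseline uses no feedback and ends at its first identification.

Metrics: PTCI is the percentage of runs whose final identification is the
true target; MNS is the mean, over correct runs, of movement steps divided by
the initial shortest-path distance (1.0 = a perfect direct path).  Headline
values average per-participant results across participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .actions import Identify, Move, Strategy
from .baselines import RandomStrategy, ReactStrategy
from .bayes import BayesStrategy
from .feedback import (
    Observation,
    ParticipantProfile,
    collapse_likelihood_to_binary,
    sample_observation,
)
from .gridworld import (
    EpisodeState,
    Grid,
    MovementClass,
    MovementEvent,
    Position,
    init_episode,
    true_movement_class,
    true_ti_class,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunRecord",
    "SweepConfig",
    "run_episode",
    "run_many",
    "ptci",
    "mns",
    "run_sweep",
    "records_to_frame",
    "aggregate_records",
    "tradeoff_correlation",
    "make_strategy",
]

VARIANTS = ("full", "no_tic", "binary")
DEFAULT_STRINGENCIES = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class RunRecord:
    """Outcome of one simulated run."""

    participant: str
    strategy: str
    variant: str
    stringency: Optional[float]
    grid_label: str
    movement_steps: int
    initial_distance: int
    identified: Optional[Position]
    correct: bool
    n_deselections: int
    capped: bool

    @property
    def normalised_steps(self) -> float:
        return self.movement_steps / self.initial_distance


def _binary_index(four_way: int) -> int:
    return 0 if four_way in (int(MovementClass.TT), int(MovementClass.TR)) else 1


def run_episode(
    strategy: Strategy,
    profile: ParticipantProfile,
    grid: Grid,
    rng: np.random.Generator,
    variant: str = "full",
    step_cap_factor: int = 50,
    stringency: Optional[float] = None,
) -> RunRecord:
    """Simulate one run to completion (or the step cap).

    ``variant``: ``full`` uses 4-way movement observations and the TI layer;
    ``no_tic`` drops the TI layer (first identification ends the run);
    ``binary`` maps each 4-way classifier draw onto {correct, error} and
    feeds the strategy 2-class observations (the strategy must then assume a
    2x2 movement matrix).  The TI layer stays on in the binary variant.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    uses_feedback = getattr(strategy, "uses_feedback", True)
    state = init_episode(grid, rng)
    strategy.reset(state, rng)
    cap = step_cap_factor * grid.n_cells
    steps = 0
    n_deselections = 0
    grid_label = f"{grid.n_rows}x{grid.n_cols}"

    def record(identified: Optional[Position], capped: bool) -> RunRecord:
        return RunRecord(
            participant=profile.id,
            strategy=strategy.name,
            variant=variant,
            stringency=stringency,
            grid_label=grid_label,
            movement_steps=steps,
            initial_distance=state.initial_distance,
            identified=identified,
            correct=(identified == state.target) and not capped,
            n_deselections=n_deselections,
            capped=capped,
        )

    action = strategy.initial_action(state, rng)
    while True:
        if isinstance(action, Move):
            if steps >= cap:
                return record(None, capped=True)
            ev = MovementEvent(state.robot, action.destination)
            true_cls = true_movement_class(ev, state.target)
            steps += 1
            state.previous = state.robot
            state.robot = action.destination
            state.t += 1
            obs: Optional[Observation] = None
            if uses_feedback:
                drawn = sample_observation(profile.movement_sampler, true_cls, rng)
                if variant == "binary":
                    obs = Observation(_binary_index(drawn.index), "movement_binary")
                else:
                    obs = drawn
            strategy.observe_movement(ev, obs, state)
        else:
            assert isinstance(action, Identify)
            pos = action.position
            if not uses_feedback or variant == "no_tic":
                return record(pos, capped=False)
            ti_true = true_ti_class(pos, state.target)
            ti_obs = sample_observation(profile.ti_sampler, ti_true, rng)
            if ti_obs.label == "CTI":
                return record(pos, capped=False)
            n_deselections += 1
            strategy.observe_ti_false(pos, state)
        action = strategy.next_action(state, rng)


def make_strategy(
    name: str,
    profile: ParticipantProfile,
    variant: str = "full",
    stringency: Optional[float] = None,
) -> Strategy:
    """Build a strategy instance for one (participant, variant) combination."""
    if name == "random":
        return RandomStrategy()
    if name == "react":
        return ReactStrategy()
    if name == "bayes":
        s = 0.1 if stringency is None else stringency
        if variant == "binary":
            movement_A = collapse_likelihood_to_binary(profile.movement_assumed)
        else:
            movement_A = profile.movement_assumed
        return BayesStrategy(movement_A, profile.ti_assumed, stringency=s)
    raise ValueError(f"unknown strategy {name!r}")


def run_many(
    strategy_name: str,
    profile: ParticipantProfile,
    grid: Grid,
    n_runs: int,
    rng: np.random.Generator,
    variant: str = "full",
    stringency: Optional[float] = None,
    step_cap_factor: int = 50,
) -> list[RunRecord]:
    """Repeat :func:`run_episode` ``n_runs`` times with a fresh strategy."""
    strategy = make_strategy(strategy_name, profile, variant, stringency)
    return [
        run_episode(
            strategy,
            profile,
            grid,
            rng,
            variant=variant,
            step_cap_factor=step_cap_factor,
            stringency=stringency,
        )
        for _ in range(n_runs)
    ]


def ptci(records: Sequence[RunRecord]) -> float:
    """Percentage of targets correctly identified."""
    if not records:
        raise ValueError("PTCI undefined on an empty record set")
    return 100.0 * sum(r.correct for r in records) / len(records)


def mns(records: Sequence[RunRecord]) -> float:
    """Mean normalised steps over correct runs; NaN when none are correct."""
    if not records:
        raise ValueError("MNS undefined on an empty record set")
    vals = [r.normalised_steps for r in records if r.correct]
    if not vals:
        return math.nan
    return float(np.mean(vals))


@dataclass
class SweepConfig:
    """Grid of simulation conditions for a multi-participant sweep."""

    profiles: Sequence[ParticipantProfile]
    grids: Sequence[tuple[int, int]] = ((9, 1), (20, 20))
    strategies: Sequence[str] = ("bayes",)
    stringencies: Sequence[float] = DEFAULT_STRINGENCIES
    variants: Sequence[str] = ("full",)
    runs_per_participant: int = 1000
    seed: int = 0
    step_cap_factor: int = 50

    def combinations(self):
        for rows, cols in self.grids:
            for strat in self.strategies:
                if strat == "bayes":
                    for variant in self.variants:
                        for s in self.stringencies:
                            yield (rows, cols, strat, variant, s)
                else:
                    if len(self.stringencies) and strat in ("react", "random"):
                        logger.warning(
                            "stringency values are ignored for the %s strategy", strat
                        )
                    yield (rows, cols, strat, "full", None)


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Run every (participant, grid, strategy, variant, stringency) cell.

    Returns one row per run; aggregate with :func:`aggregate_records`.
    Each cell gets an independent, reproducible random stream derived from
    ``cfg.seed``.
    """
    combos = list(cfg.combinations())
    frames = []
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(len(combos) * len(cfg.profiles))
    k = 0
    for rows, cols, strat, variant, s in combos:
        grid = Grid(rows, cols)
        for profile in cfg.profiles:
            rng = np.random.default_rng(streams[k])
            k += 1
            recs = run_many(
                strat,
                profile,
                grid,
                cfg.runs_per_participant,
                rng,
                variant=variant,
                stringency=s,
                step_cap_factor=cfg.step_cap_factor,
            )
            frames.append(records_to_frame(recs))
    return pd.concat(frames, ignore_index=True)


def records_to_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant": r.participant,
                "strategy": r.strategy,
                "variant": r.variant,
                "stringency": np.nan if r.stringency is None else r.stringency,
                "grid": r.grid_label,
                "movement_steps": r.movement_steps,
                "initial_distance": r.initial_distance,
                "identified_row": np.nan if r.identified is None else r.identified.row + 1,
                "identified_col": np.nan if r.identified is None else r.identified.col + 1,
                "correct": r.correct,
                "n_deselections": r.n_deselections,
                "capped": r.capped,
                "normalised_steps": r.normalised_steps,
            }
        )
    return pd.DataFrame(rows)


_GROUP = ["grid", "strategy", "variant", "stringency"]


def aggregate_records(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean ± s.d. of PTCI and MNS across participants.

    MNS for a participant is averaged over their correct runs only;
    participants with no correct run contribute no MNS value (missing, not
    zero).
    """
    per_part = []
    grouped = runs.groupby(_GROUP + ["participant"], dropna=False)
    for key, g in grouped:
        correct = g[g["correct"]]
        per_part.append(
            dict(
                zip(_GROUP + ["participant"], key),
                n_runs=len(g),
                ptci=100.0 * g["correct"].mean(),
                mns=correct["normalised_steps"].mean() if len(correct) else np.nan,
                mean_deselections=g["n_deselections"].mean(),
                n_capped=int(g["capped"].sum()),
            )
        )
    pp = pd.DataFrame(per_part)
    agg = (
        pp.groupby(_GROUP, dropna=False)
        .agg(
            n_participants=("participant", "nunique"),
            n_runs=("n_runs", "sum"),
            ptci_mean=("ptci", "mean"),
            ptci_sd=("ptci", "std"),
            mns_mean=("mns", "mean"),
            mns_sd=("mns", "std"),
            mean_deselections=("mean_deselections", "mean"),
            n_capped=("n_capped", "sum"),
        )
        .reset_index()
    )
    return agg


def tradeoff_correlation(aggregate: pd.DataFrame, grid: str, strategy: str = "bayes",
                         variant: str = "full") -> tuple[float, float]:
    """Pearson r (and p) between aggregate PTCI and MNS across stringencies."""
    from scipy import stats

    sub = aggregate[
        (aggregate["grid"] == grid)
        & (aggregate["strategy"] == strategy)
        & (aggregate["variant"] == variant)
    ].sort_values("stringency")
    if len(sub) < 3:
        raise ValueError("need at least 3 stringency rows for a correlation")
    r, p = stats.pearsonr(sub["ptci_mean"], sub["mns_mean"])
    return float(r), float(p)
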