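"""Observation model for noisy classifier feedback.

Single-trial EEG classification of the user's reaction to a robot action is
modelled as a draw from a column of a likelihood matrix ``A`` with
``A[i, j] = P(observation i | true class j)`` — the robot's model of how
reliable the classifier is for each class.  In the simulations, sampling from
a participant's *test-set* confusion table stands in for retrieving and
classifying a held-out EEG trial, while the robot reasons with an *assumed*
matrix estimated by leave-one-out cross-validation on training data; the two
tables differ in practice, which :func:`synth_participant` can emulate.

Class orderings are fixed: movements ``TT, TR, FA, SO``; identifications
``CTI, FTI``; collapsed (binary) movements ``correct, error``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gridworld import MovementClass, TIClass

__all__ = [
    "MOVEMENT_LABELS",
    "TI_LABELS",
    "BINARY_LABELS",
    "Observation",
    "ContingencyTable",
    "LikelihoodMatrix",
    "ParticipantProfile",
    "likelihood_from_counts",
    "sample_observation",
    "collapse_to_binary",
    "observation_marginal",
    "synth_participant",
    "identity_profile",
    "uniform_diagonal_profile",
]

MOVEMENT_LABELS = ("TT", "TR", "FA", "SO")
TI_LABELS = ("CTI", "FTI")
BINARY_LABELS = ("correct", "error")

_KIND_LABELS = {
    "movement": MOVEMENT_LABELS,
    "ti": TI_LABELS,
    "movement_binary": BINARY_LABELS,
}

DEFAULT_FLOOR = 1e-6


class KindError(ValueError):
    """Observation / matrix / state kinds do not match."""


def labels_for_kind(kind: str) -> tuple[str, ...]:
    try:
        return _KIND_LABELS[kind]
    except KeyError:
        raise KindError(f"unknown kind {kind!r}") from None


@dataclass(frozen=True)
class Observation:
    """A classifier output: one of ``k`` classes, one-hot encoded.

    ``index`` follows the fixed class ordering of ``kind``; the binary
    indicator form is available as :attr:`vector`.
    """

    index: int
    kind: str

    def __post_init__(self) -> None:
        k = len(labels_for_kind(self.kind))
        if not 0 <= self.index < k:
            raise ValueError(f"class index {self.index} out of range for kind {self.kind!r}")

    @property
    def k(self) -> int:
        return len(labels_for_kind(self.kind))

    @property
    def vector(self) -> np.ndarray:
        v = np.zeros(self.k)
        v[self.index] = 1.0
        return v

    @property
    def label(self) -> str:
        return labels_for_kind(self.kind)[self.index]


@dataclass(frozen=True)
class ContingencyTable:
    """Raw classification counts, indexed ``[predicted, actual]``."""

    counts: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(labels_for_kind(self.kind))
        if counts.shape != (k, k):
            raise ValueError(f"kind {self.kind!r} requires a {k}x{k} table, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("contingency counts must be nonnegative")

    @property
    def labels(self) -> tuple[str, ...]:
        return labels_for_kind(self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="predicted")

    @classmethod
    def from_csv(cls, path, kind: str) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        labels = list(labels_for_kind(kind))
        if list(df.columns) != labels or list(df.index) != labels:
            raise KindError(f"CSV header/index does not match {kind!r} class order {labels}")
        return cls(df.to_numpy(), kind)


@dataclass(frozen=True)
class LikelihoodMatrix:
    """Column-stochastic table ``A[observation, state]``.

    Every column sums to 1 and, after flooring, every entry is strictly
    positive: a single unlucky misclassification must never drive the true
    target's posterior mass to an unrecoverable zero.
    """

    entries: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        k = len(labels_for_kind(self.kind))
        if entries.shape != (k, k):
            raise ValueError(f"kind {self.kind!r} requires a {k}x{k} matrix, got {entries.shape}")
        if (entries < 0).any():
            raise ValueError("likelihood entries must be nonnegative")
        colsums = entries.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"columns must sum to 1, got {colsums}")

    @property
    def k(self) -> int:
        return self.entries.shape[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return labels_for_kind(self.kind)

    def column(self, state: int) -> np.ndarray:
        """P(observation | state) for one hidden state."""
        return self.entries[:, state]

    def state_likelihoods(self, o: Union[Observation, np.ndarray]) -> np.ndarray:
        """Likelihood of observation ``o`` under each hidden state.

        Accepts a one-hot :class:`Observation` (a row of ``A``) or a soft
        probability vector over observation classes, in which case the rows
        are averaged with those weights.
        """
        if isinstance(o, Observation):
            if o.kind != self.kind:
                raise KindError(f"observation kind {o.kind!r} vs matrix kind {self.kind!r}")
            return self.entries[o.index, :]
        w = np.asarray(o, dtype=float)
        if w.shape != (self.k,):
            raise KindError(f"soft observation must have length {self.k}")
        return w @ self.entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="observation")

    @classmethod
    def from_csv(cls, path, kind: str) -> "LikelihoodMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = list(labels_for_kind(kind))
        if list(df.columns) != labels or list(df.index) != labels:
            raise KindError(f"CSV header/index does not match {kind!r} class order {labels}")
        return cls(df.to_numpy(), kind)

    @classmethod
    def identity(cls, kind: str) -> "LikelihoodMatrix":
        return cls(np.eye(len(labels_for_kind(kind))), kind)

    @classmethod
    def uniform_diagonal(cls, kind: str, diagonal: float) -> "LikelihoodMatrix":
        """Matrix with ``diagonal`` on-diagonal and the remaining mass spread
        evenly off-diagonal in each column."""
        k = len(labels_for_kind(kind))
        if not 0.0 <= diagonal <= 1.0:
            raise ValueError("diagonal accuracy must lie in [0, 1]")
        off = (1.0 - diagonal) / (k - 1)
        m = np.full((k, k), off)
        np.fill_diagonal(m, diagonal)
        return cls(m, kind)


def likelihood_from_counts(
    table: ContingencyTable, floor: float = DEFAULT_FLOOR
) -> LikelihoodMatrix:
    """Column-normalise a contingency table into a likelihood matrix.

    Entries are floored at ``floor`` and the columns re-normalised, so no
    observation ever has exactly zero likelihood under any state.
    """
    counts = table.counts.astype(float)
    colsums = counts.sum(axis=0)
    if (colsums == 0).any():
        bad = [table.labels[j] for j in np.nonzero(colsums == 0)[0]]
        raise ValueError(f"degenerate class(es) with zero trials: {bad}")
    m = counts / colsums
    if floor > 0:
        m = np.maximum(m, floor)
        m = m / m.sum(axis=0)
    return LikelihoodMatrix(m, table.kind)


def sample_observation(
    m: LikelihoodMatrix,
    true_state: Union[int, MovementClass, TIClass],
    rng: np.random.Generator,
) -> Observation:
    """Draw a classifier output for an action of class ``true_state``.

    Stands in for retrieving a held-out EEG trial of that class and running
    it through the trained classifier.
    """
    state = int(true_state)
    if not 0 <= state < m.k:
        raise KindError(f"state {true_state!r} does not index a column of a {m.kind!r} matrix")
    idx = int(rng.choice(m.k, p=m.column(state)))
    return Observation(idx, m.kind)


def collapse_to_binary(t4: ContingencyTable) -> ContingencyTable:
    """Sum a 4x4 movement table into 2x2 {correct = TT+TR, error = FA+SO}."""
    if t4.kind != "movement":
        raise KindError("collapse_to_binary expects a 4x4 movement table")
    groups = [[MovementClass.TT, MovementClass.TR], [MovementClass.FA, MovementClass.SO]]
    out = np.zeros((2, 2), dtype=np.int64)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            out[i, j] = t4.counts[np.ix_(gi, gj)].sum()
    return ContingencyTable(out, "movement_binary")


def collapse_likelihood_to_binary(m: LikelihoodMatrix) -> LikelihoodMatrix:
    """Collapse a 4x4 movement likelihood into the 2x2 correct/error form.

    Column groups are averaged (each column is a distribution; grouping the
    hidden states assumes they are equally weighted within a group) and row
    groups summed.
    """
    if m.kind != "movement":
        raise KindError("expects a 4x4 movement likelihood")
    groups = [[MovementClass.TT, MovementClass.TR], [MovementClass.FA, MovementClass.SO]]
    out = np.zeros((2, 2))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            out[i, j] = m.entries[np.ix_(gi, gj)].sum() / len(gj)
    return LikelihoodMatrix(out, "movement_binary")


def observation_marginal(m: LikelihoodMatrix, o: Observation) -> float:
    """P(O) under a uniform prior over hidden states: the row sum for ``o``
    divided by the sum of all entries (equals row-sum / k for a
    column-stochastic matrix)."""
    if o.kind != m.kind:
        raise KindError(f"observation kind {o.kind!r} vs matrix kind {m.kind!r}")
    return float(m.entries[o.index, :].sum() / m.entries.sum())


@dataclass(frozen=True)
class ParticipantProfile:
    """A virtual subject.

    ``*_sampler`` matrices reproduce the subject's test-set classification
    behaviour (used to generate observations); ``*_assumed`` matrices are
    what the robot believes about its classifier (in the study, a
    leave-one-out estimate from training data).
    """

    movement_sampler: LikelihoodMatrix
    movement_assumed: LikelihoodMatrix
    ti_sampler: LikelihoodMatrix
    ti_assumed: LikelihoodMatrix
    id: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("movement_sampler", "movement_assumed"):
            if getattr(self, name).kind != "movement":
                raise KindError(f"{name} must have kind 'movement'")
        for name in ("ti_sampler", "ti_assumed"):
            if getattr(self, name).kind != "ti":
                raise KindError(f"{name} must have kind 'ti'")


def _draw_confusion(
    k: int, accuracy_ranges: Sequence[tuple[float, float]], rng: np.random.Generator
) -> np.ndarray:
    cols = []
    for j in range(k):
        lo, hi = accuracy_ranges[j]
        acc = float(rng.uniform(lo, hi))
        col = np.zeros(k)
        col[j] = acc
        if k > 1:
            off = rng.dirichlet(np.ones(k - 1)) * (1.0 - acc)
            col[np.arange(k) != j] = off
        cols.append(col)
    return np.column_stack(cols)


def synth_participant(
    movement_accuracy: Union[tuple[float, float], Sequence[tuple[float, float]]] = (0.45, 0.80),
    ti_accuracy: Union[tuple[float, float], Sequence[tuple[float, float]]] = (0.60, 0.90),
    rng: Optional[np.random.Generator] = None,
    mismatch: float = 0.0,
    floor: float = DEFAULT_FLOOR,
    id: str = "synthetic",
) -> ParticipantProfile:
    """Generate a virtual subject's confusion behaviour.

    Per-class diagonal accuracies are drawn uniformly from the given ranges
    (a single ``(lo, hi)`` pair applies to every class) and the residual
    probability mass is spread over the off-diagonal entries of each column
    with flat Dirichlet weights.  ``mismatch`` in [0, 1] blends the assumed
    matrices towards an independent draw, emulating the discrepancy between a
    leave-one-out estimate and true test-set behaviour; 0 means the robot's
    model is exact.
    """
    rng = np.random.default_rng() if rng is None else rng
    if mismatch < 0:
        raise ValueError("mismatch must be nonnegative")

    def expand(ranges, k):
        r = np.asarray(ranges, dtype=float)
        if r.shape == (2,):
            r = np.tile(r, (k, 1))
        if r.shape != (k, 2):
            raise ValueError(f"need {k} (lo, hi) accuracy intervals, got shape {r.shape}")
        for lo, hi in r:
            if not (1.0 / k < lo <= hi <= 1.0):
                raise ValueError(f"accuracy interval ({lo}, {hi}) outside (1/{k}, 1]")
        return [tuple(row) for row in r]

    out = {}
    for prefix, kind, ranges in (
        ("movement", "movement", movement_accuracy),
        ("ti", "ti", ti_accuracy),
    ):
        k = len(labels_for_kind(kind))
        ranges = expand(ranges, k)
        sampler = _draw_confusion(k, ranges, rng)
        if mismatch > 0:
            other = _draw_confusion(k, ranges, rng)
            assumed = (1.0 - mismatch) * sampler + mismatch * other
        else:
            assumed = sampler.copy()

        def finish(m):
            m = np.maximum(m, floor)
            return LikelihoodMatrix(m / m.sum(axis=0), kind)

        out[f"{prefix}_sampler"] = finish(sampler)
        out[f"{prefix}_assumed"] = finish(assumed)
    return ParticipantProfile(id=id, **out)


def identity_profile(id: str = "identity") -> ParticipantProfile:
    """Perfect-classifier profile: every observation equals the true class."""
    m = LikelihoodMatrix.identity("movement")
    t = LikelihoodMatrix.identity("ti")
    return ParticipantProfile(m, m, t, t, id=id)


def uniform_diagonal_profile(
    movement_diagonal: float, ti_diagonal: float, id: str = "diag"
) -> ParticipantProfile:
    """Profile with fixed per-class accuracy and symmetric confusions."""
    m = LikelihoodMatrix.uniform_diagonal("movement", movement_diagonal)
    t = LikelihoodMatrix.uniform_diagonal("ti", ti_diagonal)
    return ParticipantProfile(m, m, t, t, id=id)
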