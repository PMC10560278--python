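"""ERP classification layer: preprocessing, stepwise LDA, and synthetic ERPs.

Event-locked 8-channel EEG epochs are band-pass filtered, downsampled to
64 Hz, baseline-corrected on the −200–0 ms window, and the 200–700 ms
post-event window concatenated across channels into a 256-dimensional
feature vector.  Binary classifiers use stepwise linear discriminant
analysis (SWLDA): forward-entry / backward-removal stepwise selection on a
least-squares regression of the class labels, which yields the small,
highly discriminative feature sets that work well with the short and
imbalanced trial counts typical of this paradigm.

Four-way movement classification is a two-stage binary tree — stage 1
separates correct (TT, TR) from erroneous (FA, SO) movements on 1–10 Hz
features, stage 2 subclassifies within the branch on 1–32 Hz features — and
a separate binary SWLDA classifies target identifications (CTI vs FTI) on
1–10 Hz features.  Leave-one-out cross-validation over the training epochs
produces the contingency table from which the robot's assumed likelihood
matrix is built.

A synthetic ERP generator emulates the qualitative structure of the grand
averages: erroneous actions evoke larger fronto-central deflections than
correct ones, with class-specific amplitudes and latencies, plus 1/f
coloured noise and trial-level amplitude jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal, stats

from .feedback import ContingencyTable, LikelihoodMatrix, likelihood_from_counts
from .gridworld import MovementClass, TIClass

__all__ = [
    "CHANNELS",
    "EEGEpoch",
    "PreprocessConfig",
    "STAGE1_CONFIG",
    "STAGE2_CONFIG",
    "TI_CONFIG",
    "SWLDAModel",
    "ClassifierTree",
    "preprocess_epoch",
    "preprocess_epochs",
    "swlda_fit",
    "fit_movement_tree",
    "fit_ti_model",
    "classify_movement",
    "classify_ti",
    "loo_likelihood",
    "ERPTemplateSet",
    "default_movement_templates",
    "default_ti_templates",
    "generate_synthetic_epochs",
    "train_test_split_epochs",
    "paradigm_class_counts",
    "save_epochs",
    "load_epochs",
]

CHANNELS = ("Fz", "Cz", "Oz", "Pz", "C3", "C4", "PO7", "PO8")
NATIVE_RATE = 500.0


@dataclass
class EEGEpoch:
    """One event-locked multichannel trial.

    ``event_index`` is the sample index of action onset; the epoch must span
    at least −200 ms to +700 ms around it.
    """

    signal: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    event_index: int
    label: int
    kind: str = "movement"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("epoch signal must be channels x samples")
        fs = self.sampling_rate
        pre = self.event_index / fs
        post = (self.signal.shape[1] - 1 - self.event_index) / fs
        if pre < 0.2 - 1e-9 or post < 0.7 - 1e-9:
            raise ValueError(
                f"epoch must span at least -200..+700 ms around the event "
                f"(got -{pre * 1e3:.0f}..+{post * 1e3:.0f} ms)"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering / epoching parameters for one classifier stage."""

    passband: tuple[float, float]
    downsample_to: float = 64.0
    window: tuple[float, float] = (0.2, 0.7)  # seconds post-event, half-open
    baseline: tuple[float, float] = (-0.2, 0.0)
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.passband[1] > self.downsample_to / 2:
            raise ValueError("passband upper edge exceeds the downsampled Nyquist rate")

    @property
    def n_window_samples(self) -> int:
        return int(round((self.window[1] - self.window[0]) * self.downsample_to))


STAGE1_CONFIG = PreprocessConfig(passband=(1.0, 10.0))
STAGE2_CONFIG = PreprocessConfig(passband=(1.0, 32.0))
TI_CONFIG = PreprocessConfig(passband=(1.0, 10.0))


def preprocess_epoch(e: EEGEpoch, cfg: PreprocessConfig) -> np.ndarray:
    """Band-pass, downsample, baseline-correct, window, and flatten an epoch.

    Returns a vector of length ``n_channels * n_window_samples`` (8 x 32 =
    256 for the standard configuration); the post-event window is half-open
    [200, 700) ms so the count is deterministic.
    """
    fs = e.sampling_rate
    sos = signal.butter(
        cfg.filter_order, cfg.passband, btype="bandpass", fs=fs, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, e.signal, axis=1)

    ratio = Fraction(cfg.downsample_to / fs).limit_denominator(1000)
    down = signal.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=1)
    new_rate = fs * ratio.numerator / ratio.denominator
    event = e.event_index * ratio.numerator / ratio.denominator
    t = (np.arange(down.shape[1]) - event) / new_rate

    bl = (t >= cfg.baseline[0] - 1e-9) & (t < cfg.baseline[1] - 1e-9)
    if not bl.any():
        raise ValueError("baseline window outside epoch")
    down = down - down[:, bl].mean(axis=1, keepdims=True)

    start_idx = np.nonzero(t >= cfg.window[0] - 1e-9)[0]
    n = cfg.n_window_samples
    if len(start_idx) == 0 or start_idx[0] + n > down.shape[1]:
        raise ValueError("post-event window outside epoch")
    w = down[:, start_idx[0] : start_idx[0] + n]
    return w.ravel()


def preprocess_epochs(epochs: Sequence[EEGEpoch], cfg: PreprocessConfig) -> np.ndarray:
    return np.vstack([preprocess_epoch(e, cfg) for e in epochs])


# ---------------------------------------------------------------------------
# stepwise LDA


@dataclass
class SWLDAModel:
    """A fitted stepwise-LDA binary classifier.

    ``weights`` are the least-squares regression coefficients (labels coded
    −1/+1) on the selected features; the decision score's sign gives the
    predicted class (positive → class 1).
    """

    selected_features: list[int]
    weights: np.ndarray
    intercept: float
    entry_p: float
    removal_p: float
    max_features: int
    trace: list[tuple[str, int, float]] = field(default_factory=list, repr=False)

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected_features:
            return X[:, self.selected_features] @ self.weights + self.intercept
        return np.full(X.shape[0], self.intercept)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def swlda_fit(
    features: np.ndarray,
    labels: np.ndarray,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_features: int = 60,
) -> SWLDAModel:
    """Forward-entry / backward-removal stepwise regression of binary labels.

    At each forward step the candidate whose partial F-test has the smallest
    p-value enters if p < ``entry_p``; backward steps then remove any selected
    feature whose coefficient t-test has p > ``removal_p``.  Iteration stops
    at convergence, on a revisited feature set, or at ``max_features``.
    Implemented on Gram matrices so each sweep over candidates is a single
    vectorised solve.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly 2 classes, got {classes}")
    yc = np.where(y == classes[1], 1.0, -1.0)

    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    G = Xa.T @ Xa
    gy = Xa.T @ yc
    yy = float(yc @ yc)
    diag = np.diag(G).copy()

    S = [0]  # intercept, always in, never counted
    in_model = np.zeros(p + 1, dtype=bool)
    in_model[0] = True
    trace: list[tuple[str, int, float]] = []
    seen: set[frozenset[int]] = set()

    for _ in range(4 * max_features + 8):
        changed = False
        A = G[np.ix_(S, S)]
        beta = np.linalg.solve(A, gy[S])
        rss = max(yy - gy[S] @ beta, 0.0)

        # forward entry
        if len(S) - 1 < max_features:
            cand = np.nonzero(~in_model)[0]
            if len(cand):
                B = G[np.ix_(S, cand)]
                AinvB = np.linalg.solve(A, B)
                d = diag[cand] - np.einsum("ij,ij->j", B, AinvB)
                c = gy[cand] - B.T @ beta
                ok = d > 1e-10 * np.maximum(diag[cand], 1.0)
                df = n - (len(S) + 1)
                if df > 0 and ok.any():
                    with np.errstate(divide="ignore", invalid="ignore"):
                        drss = np.where(ok, c**2 / np.where(ok, d, 1.0), 0.0)
                        resid = np.maximum(rss - drss, 0.0)
                        F = np.where(resid > 0, drss / (resid / df), np.inf)
                    pvals = stats.f.sf(F, 1, df)
                    pvals[~ok] = 1.0
                    best = int(np.argmin(pvals))
                    if pvals[best] < entry_p:
                        j = int(cand[best])
                        S.append(j)
                        in_model[j] = True
                        trace.append(("add", j - 1, float(pvals[best])))
                        changed = True

        # backward removal (repeat until all retained features qualify)
        while len(S) > 1:
            A = G[np.ix_(S, S)]
            Ainv = np.linalg.inv(A)
            beta = Ainv @ gy[S]
            rss = max(yy - gy[S] @ beta, 0.0)
            df = n - len(S)
            if df <= 0:
                break
            sigma2 = rss / df
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals = beta / np.sqrt(np.maximum(sigma2 * np.diag(Ainv), 1e-300))
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
            worst_i = 1 + int(np.argmax(pvals[1:]))
            if pvals[worst_i] > removal_p:
                j = S.pop(worst_i)
                in_model[j] = False
                trace.append(("remove", j - 1, float(pvals[worst_i])))
                changed = True
            else:
                break

        key = frozenset(S)
        if not changed or key in seen:
            break
        seen.add(key)

    A = G[np.ix_(S, S)]
    beta = np.linalg.solve(A, gy[S])
    selected = [j - 1 for j in S[1:]]
    return SWLDAModel(
        selected_features=selected,
        weights=beta[1:],
        intercept=float(beta[0]),
        entry_p=entry_p,
        removal_p=removal_p,
        max_features=max_features,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# 2-stage movement tree and TI classifier


@dataclass
class ClassifierTree:
    """Two-stage movement classifier plus the binary TI classifier.

    Stage 1 (correct vs error) and the TI model use 1–10 Hz features;
    stage-2 subclassifiers use 1–32 Hz features.  Stage-2 models are trained
    only on epochs whose true class belongs to their branch.
    """

    stage1: SWLDAModel
    stage2_correct: SWLDAModel
    stage2_error: SWLDAModel
    ti: Optional[SWLDAModel] = None
    stage1_config: PreprocessConfig = STAGE1_CONFIG
    stage2_config: PreprocessConfig = STAGE2_CONFIG
    ti_config: PreprocessConfig = TI_CONFIG


_CORRECT = (int(MovementClass.TT), int(MovementClass.TR))
_ERROR = (int(MovementClass.FA), int(MovementClass.SO))


def _fit_tree_features(
    f1: np.ndarray, f2: np.ndarray, labels: np.ndarray, **swlda_params
) -> ClassifierTree:
    labels = np.asarray(labels, dtype=int)
    is_err = np.isin(labels, _ERROR).astype(int)
    stage1 = swlda_fit(f1, is_err, **swlda_params)
    corr = np.isin(labels, _CORRECT)
    err = ~corr
    stage2_correct = swlda_fit(
        f2[corr], (labels[corr] == int(MovementClass.TR)).astype(int), **swlda_params
    )
    stage2_error = swlda_fit(
        f2[err], (labels[err] == int(MovementClass.SO)).astype(int), **swlda_params
    )
    return ClassifierTree(stage1, stage2_correct, stage2_error)


def _classify_tree_features(
    tree: ClassifierTree, f1: np.ndarray, f2: np.ndarray, return_trace: bool = False
):
    is_err = bool(tree.stage1.predict(f1)[0])
    if is_err:
        pred = int(MovementClass.SO) if tree.stage2_error.predict(f2)[0] else int(MovementClass.FA)
    else:
        pred = int(MovementClass.TR) if tree.stage2_correct.predict(f2)[0] else int(MovementClass.TT)
    if return_trace:
        return pred, ("error" if is_err else "correct")
    return pred


def fit_movement_tree(
    epochs: Sequence[EEGEpoch],
    labels: Optional[Sequence[int]] = None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_features: int = 60,
) -> ClassifierTree:
    """Fit the 2-stage movement tree on labelled epochs."""
    if labels is None:
        labels = [e.label for e in epochs]
    labels = np.asarray(labels, dtype=int)
    for cls in MovementClass:
        if (labels == int(cls)).sum() < 2:
            raise ValueError(f"need at least 2 epochs of class {cls.name}")
    f1 = preprocess_epochs(epochs, STAGE1_CONFIG)
    f2 = preprocess_epochs(epochs, STAGE2_CONFIG)
    return _fit_tree_features(
        f1, f2, labels, entry_p=entry_p, removal_p=removal_p, max_features=max_features
    )


def fit_ti_model(
    epochs: Sequence[EEGEpoch],
    labels: Optional[Sequence[int]] = None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_features: int = 60,
) -> SWLDAModel:
    """Fit the binary CTI-vs-FTI classifier."""
    if labels is None:
        labels = [e.label for e in epochs]
    labels = np.asarray(labels, dtype=int)
    f = preprocess_epochs(epochs, TI_CONFIG)
    return swlda_fit(
        f, (labels == int(TIClass.FTI)).astype(int),
        entry_p=entry_p, removal_p=removal_p, max_features=max_features,
    )


def classify_movement(
    tree: ClassifierTree, e: EEGEpoch, return_trace: bool = False
) -> Union[int, tuple[int, str]]:
    """Route one epoch through the tree; returns the 4-way class index.

    With ``return_trace`` also returns which stage-2 branch ran."""
    f1 = preprocess_epoch(e, tree.stage1_config)
    f2 = preprocess_epoch(e, tree.stage2_config)
    return _classify_tree_features(tree, f1[None, :], f2[None, :], return_trace)


def classify_ti(model: SWLDAModel, e: EEGEpoch) -> int:
    """CTI (0) or FTI (1) for one identification epoch."""
    f = preprocess_epoch(e, TI_CONFIG)
    return int(TIClass.FTI) if model.predict(f[None, :])[0] else int(TIClass.CTI)


def loo_likelihood(
    epochs: Sequence[EEGEpoch],
    labels: Optional[Sequence[int]] = None,
    kind: str = "movement",
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_features: int = 60,
    floor: float = 1e-6,
) -> tuple[LikelihoodMatrix, ContingencyTable]:
    """Leave-one-out estimate of the classifier's confusion behaviour.

    Each epoch is classified by a model fitted on all the others; the
    accumulated predicted-by-actual counts become the likelihood matrix the
    robot assumes during navigation.  Features are precomputed once (the
    preprocessing is per-epoch, so it is unaffected by the held-out fold).
    """
    if labels is None:
        labels = [e.label for e in epochs]
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    params = dict(entry_p=entry_p, removal_p=removal_p, max_features=max_features)

    if kind == "movement":
        k = 4
        classes = [int(c) for c in MovementClass]
    elif kind == "ti":
        k = 2
        classes = [int(c) for c in TIClass]
    else:
        raise ValueError(f"kind must be 'movement' or 'ti', got {kind!r}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"leave-one-out needs >= 2 epochs per class (class {c} short)")

    counts = np.zeros((k, k), dtype=np.int64)
    if kind == "movement":
        f1 = preprocess_epochs(epochs, STAGE1_CONFIG)
        f2 = preprocess_epochs(epochs, STAGE2_CONFIG)
        for i in range(n):
            keep = np.arange(n) != i
            tree = _fit_tree_features(f1[keep], f2[keep], labels[keep], **params)
            pred = _classify_tree_features(tree, f1[i : i + 1], f2[i : i + 1])
            counts[pred, labels[i]] += 1
    else:
        f = preprocess_epochs(epochs, TI_CONFIG)
        yb = (labels == int(TIClass.FTI)).astype(int)
        for i in range(n):
            keep = np.arange(n) != i
            model = swlda_fit(f[keep], yb[keep], **params)
            pred = int(TIClass.FTI) if model.predict(f[i : i + 1])[0] else int(TIClass.CTI)
            counts[pred, labels[i]] += 1

    table = ContingencyTable(counts, "movement" if kind == "movement" else "ti")
    return likelihood_from_counts(table, floor=floor), table


# ---------------------------------------------------------------------------
# synthetic ERP generation

# fronto-central scalp weighting of the ErrP components
_TOPOGRAPHY = np.array([0.9, 1.0, 0.35, 0.8, 0.55, 0.55, 0.3, 0.3])


def _waveform(t: np.ndarray, components: Sequence[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian bumps (amplitude, latency s, width s)."""
    w = np.zeros_like(t)
    for amp, mu, sd in components:
        w += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return w


@dataclass
class ERPTemplateSet:
    """Per-class noise-free template waveforms plus a trial noise model.

    ``templates`` has shape (n_classes, n_channels, n_samples).  Trials are
    ``template * (1 + jitter)`` plus 1/f-coloured noise scaled to
    ``noise_scale`` (same units as the templates; 0 gives exact templates).
    """

    kind: str
    templates: np.ndarray
    sampling_rate: float = NATIVE_RATE
    tmin: float = -0.3
    amplitude_jitter: float = 0.25
    noise_exponent: float = 1.0
    noise_scale: float = 3.0

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]

    @property
    def event_index(self) -> int:
        return int(round(-self.tmin * self.sampling_rate))

    def peak_amplitudes(self) -> np.ndarray:
        return np.abs(self.templates).max(axis=(1, 2))


def _build_templates(
    kind: str, components_per_class: Sequence[Sequence[tuple[float, float, float]]],
    tmin: float = -0.3, tmax: float = 0.9, fs: float = NATIVE_RATE,
) -> ERPTemplateSet:
    n = int(round((tmax - tmin) * fs))
    t = tmin + np.arange(n) / fs
    temps = []
    for comps in components_per_class:
        wave = _waveform(t, comps)
        temps.append(np.outer(_TOPOGRAPHY, wave))
    return ERPTemplateSet(kind=kind, templates=np.stack(temps), sampling_rate=fs, tmin=tmin)


def default_movement_templates() -> ERPTemplateSet:
    """Templates for TT, TR, FA, SO (in fixed class order).

    Erroneous movements (FA, SO) carry larger deflections than correct ones,
    the target-reached response exceeds plain towards-target, and
    stepping-off exceeds moving-further-away; latencies differ slightly so
    the classes are separable at high signal-to-noise ratio.  Amplitudes are
    in arbitrary microvolt-like units.
    """
    return _build_templates(
        "movement",
        [
            [(3.0, 0.30, 0.06)],                        # TT
            [(4.0, 0.45, 0.06)],                        # TR
            [(-3.0, 0.25, 0.05), (5.0, 0.33, 0.06)],    # FA
            [(-4.0, 0.27, 0.05), (7.0, 0.50, 0.07)],    # SO
        ],
    )


def default_ti_templates() -> ERPTemplateSet:
    """Templates for CTI, FTI; the false identification (an error) is larger."""
    return _build_templates(
        "ti",
        [
            [(3.0, 0.36, 0.09)],                       # CTI
            [(-3.5, 0.27, 0.05), (7.0, 0.38, 0.08)],   # FTI
        ],
    )


def _colored_noise(
    shape: tuple[int, int], exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS noise with a 1/f**exponent power spectrum per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n, axis=1)
    rms = out.std(axis=1, keepdims=True)
    return out / np.maximum(rms, 1e-12)


def generate_synthetic_epochs(
    t: ERPTemplateSet,
    n_per_class: Union[int, Sequence[int]],
    rng: np.random.Generator,
    noise_scale: Optional[float] = None,
) -> list[EEGEpoch]:
    """Draw labelled epochs: jittered class template plus coloured noise."""
    if np.isscalar(n_per_class):
        n_per_class = [int(n_per_class)] * t.n_classes
    if len(n_per_class) != t.n_classes:
        raise ValueError(f"need {t.n_classes} class counts")
    scale = t.noise_scale if noise_scale is None else float(noise_scale)
    epochs = []
    for cls, n in enumerate(n_per_class):
        for _ in range(int(n)):
            jitter = max(0.1, 1.0 + t.amplitude_jitter * rng.standard_normal())
            sig = t.templates[cls] * jitter
            if scale > 0:
                sig = sig + scale * _colored_noise(sig.shape, t.noise_exponent, rng)
            epochs.append(
                EEGEpoch(sig, t.sampling_rate, t.event_index, label=cls, kind=t.kind)
            )
    return epochs


def train_test_split_epochs(
    epochs: Sequence[EEGEpoch],
    rng: np.random.Generator,
    test_fraction: float = 0.15,
) -> tuple[list[EEGEpoch], list[EEGEpoch]]:
    """Stratified split: within each class, ``test_fraction`` of trials
    (at least one) are held out as the test set."""
    by_class: dict[int, list[EEGEpoch]] = {}
    for e in epochs:
        by_class.setdefault(e.label, []).append(e)
    train, test = [], []
    for cls in sorted(by_class):
        items = list(by_class[cls])
        order = rng.permutation(len(items))
        n_test = max(1, int(round(test_fraction * len(items))))
        for k, idx in enumerate(order):
            (test if k < n_test else train).append(items[idx])
    return train, test


# preset action probabilities of the acquisition paradigm: off the target the
# scripted robot moves towards with p=0.7, further away with p=0.2, and falsely
# identifies with p=0.1; on the target it identifies with p=0.67 and steps off
# with p=0.33
PARADIGM_OFF_TARGET = {"towards": 0.7, "away": 0.2, "identify": 0.1}
PARADIGM_ON_TARGET = {"identify": 0.67, "step_off": 0.33}


def paradigm_class_counts(
    n_runs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-frequency imbalance induced by the scripted acquisition paradigm.

    Simulates ``n_runs`` runs of the 9-cell 1-D display (target uniform,
    cursor starting 2 or 3 cells away, preset action probabilities) and
    returns (movement-class counts [TT, TR, FA, SO], identification counts
    [CTI, FTI]).  Useful as realistic ``n_per_class`` values for
    :func:`generate_synthetic_epochs`.
    """
    move_counts = np.zeros(4, dtype=np.int64)
    ti_counts = np.zeros(2, dtype=np.int64)
    n_cells = 9
    for _ in range(n_runs):
        target = int(rng.integers(n_cells))
        offsets = [d for d in (-3, -2, 2, 3) if 0 <= target + d < n_cells]
        pos = target + offsets[int(rng.integers(len(offsets)))]
        while True:
            if pos == target:
                if rng.random() < PARADIGM_ON_TARGET["identify"]:
                    ti_counts[int(TIClass.CTI)] += 1
                    break
                step = [q for q in (pos - 1, pos + 1) if 0 <= q < n_cells]
                pos = step[int(rng.integers(len(step)))]
                move_counts[int(MovementClass.SO)] += 1
            else:
                u = rng.random()
                if u < PARADIGM_OFF_TARGET["identify"]:
                    ti_counts[int(TIClass.FTI)] += 1
                    break
                towards = pos + (1 if target > pos else -1)
                away = pos - (1 if target > pos else -1)
                # an away move may be blocked by the wall; move towards instead
                go_away = (
                    u < PARADIGM_OFF_TARGET["identify"] + PARADIGM_OFF_TARGET["away"]
                    and 0 <= away < n_cells
                )
                if go_away:
                    pos = away
                    move_counts[int(MovementClass.FA)] += 1
                else:
                    pos = towards
                    if pos == target:
                        move_counts[int(MovementClass.TR)] += 1
                    else:
                        move_counts[int(MovementClass.TT)] += 1
    return move_counts, ti_counts


def save_epochs(epochs: Sequence[EEGEpoch], directory) -> Path:
    """Write epochs as per-epoch CSV matrices plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, e in enumerate(epochs):
        fname = f"epoch_{i:05d}.csv"
        np.savetxt(directory / fname, e.signal, delimiter=",")
        rows.append(
            dict(
                file=fname,
                label=e.label,
                kind=e.kind,
                sampling_rate=e.sampling_rate,
                event_index=e.event_index,
            )
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_epochs(manifest) -> list[EEGEpoch]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    epochs = []
    for _, row in df.iterrows():
        sig = np.loadtxt(manifest.parent / row["file"], delimiter=",")
        epochs.append(
            EEGEpoch(
                sig,
                float(row["sampling_rate"]),
                int(row["event_index"]),
                int(row["label"]),
                str(row["kind"]),
            )
        )
    return epochs
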