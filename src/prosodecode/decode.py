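"""Logistic decoding of closing phrase boundaries with cross-condition
generalization.

The decoder is always trained on the neutral (weak-prosody, class-
balanced) pool and evaluated by AUC on the fixed neutral / coherent /
incoherent test sets.  Two readouts are provided: whole-window MVPA
(features = all components x samples inside a 400 ms window, tenfold
randomized cross-validation, C = 1) and per-timepoint temporal decoding
(one classifier per sample, C selected by nested fivefold
cross-validation over a log-spaced grid from 1e-5 to 1e5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .epochs import EpochSet

__all__ = [
    "MvpaResult",
    "TemporalResult",
    "fit_logistic",
    "compute_auc",
    "mvpa_decode",
    "temporal_decode",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = np.logspace(-5, 5, 11)


@dataclass
class MvpaResult:
    """Whole-window decoding AUCs for one subject and one window."""

    mean_auc: dict  # condition -> mean AUC over folds
    fold_aucs: dict  # condition -> array of per-fold AUCs
    window: tuple
    C: float
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "mean_auc": {k: float(v) for k, v in self.mean_auc.items()},
            "fold_aucs": {k: np.asarray(v).tolist() for k, v in self.fold_aucs.items()},
            "window": list(self.window),
            "C": self.C,
            "n_folds": self.n_folds,
        }


@dataclass
class TemporalResult:
    """Per-timepoint decoding AUC traces for one subject."""

    auc: dict  # condition -> array over timepoints
    times: np.ndarray
    selected_C: np.ndarray  # chosen regularization per timepoint

    def to_dict(self) -> dict:
        return {
            "auc": {k: np.asarray(v).tolist() for k, v in self.auc.items()},
            "times": self.times.tolist(),
            "selected_C": self.selected_C.tolist(),
        }


def fit_logistic(X, y, C: float = 1.0, tol: float = 1e-6) -> LogisticRegression:
    """Fit an L2-penalized logistic classifier (penalty strength 1/C)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if C <= 0:
        raise ValueError("C must be > 0")
    model = LogisticRegression(C=C, solver="lbfgs", tol=tol, max_iter=2000)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def compute_auc(scores, y) -> float:
    """Area under the ROC curve: probability a random positive outscores a
    random negative, ties counted 1/2."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _window_features(epochs: EpochSet, t0: float, t1: float) -> np.ndarray:
    win = epochs.time_window(t0, t1)
    return win.data.reshape(len(win), -1)


def _zscore_train(Xtr: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def mvpa_decode(
    train: EpochSet,
    tests: dict,
    window: tuple = (0.0, 0.4),
    C: float = 1.0,
    n_folds: int = 10,
    rng: np.random.Generator | int | None = None,
) -> MvpaResult:
    """Whole-window MVPA with tenfold randomized cross-validation.

    Per fold, the classifier is fitted on nine tenths of the training
    pool (features z-scored by that portion's statistics) and scored on
    the three fixed test sets; the held-out training tenth is not used
    for scoring.  Returns per-condition AUC averaged over folds.
    """
    t0, t1 = window
    Xtr_full = _window_features(train, t0, t1)
    ytr = np.asarray(train.labels).astype(int)
    test_feats = {
        cond: (_window_features(es, t0, t1), np.asarray(es.labels).astype(int))
        for cond, es in tests.items()
    }
    seed = int(np.random.default_rng(rng).integers(2**31))
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)

    fold_aucs = {cond: [] for cond in tests}
    for fit_idx, _ in folds.split(Xtr_full):
        Xf, yf = Xtr_full[fit_idx], ytr[fit_idx]
        mu, sd = _zscore_train(Xf)
        model = fit_logistic((Xf - mu) / sd, yf, C=C)
        for cond, (Xt, yt) in test_feats.items():
            scores = model.decision_function((Xt - mu) / sd)
            fold_aucs[cond].append(compute_auc(scores, yt))
    return MvpaResult(
        mean_auc={c: float(np.mean(v)) for c, v in fold_aucs.items()},
        fold_aucs={c: np.asarray(v) for c, v in fold_aucs.items()},
        window=window,
        C=C,
        n_folds=n_folds,
    )


def _select_C(X, y, C_grid, inner_folds, seed) -> float:
    """Inner-CV grid search; ties broken toward the smallest C.

    The regularization path is walked with a warm-started solver per
    fold, which does not change the optimum (the loss is strictly convex)
    but cuts iterations substantially.
    """
    folds = list(
        KFold(n_splits=inner_folds, shuffle=True, random_state=seed).split(X)
    )
    grid = np.sort(np.asarray(C_grid, dtype=float))
    scores = np.zeros((len(grid), len(folds)))
    counts = np.zeros(len(grid))
    for fi, (tr, va) in enumerate(folds):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        mu, sd = _zscore_train(X[tr])
        Xtr = (X[tr] - mu) / sd
        Xva = (X[va] - mu) / sd
        model = LogisticRegression(
            solver="lbfgs", tol=1e-6, max_iter=2000, warm_start=True
        )
        for ci, C in enumerate(grid):
            model.set_params(C=C)
            model.fit(Xtr, y[tr])
            scores[ci, fi] = compute_auc(model.decision_function(Xva), y[va])
            counts[ci] += 1
    valid = counts > 0
    if not valid.any():
        return float(grid[0])
    mean_scores = np.where(valid, scores.sum(axis=1) / np.maximum(counts, 1), -np.inf)
    # argmax returns the first (= smallest C) maximizer
    return float(grid[int(np.argmax(mean_scores))])


def temporal_decode(
    train: EpochSet,
    tests: dict,
    C_grid=DEFAULT_C_GRID,
    inner_folds: int = 5,
    rng: np.random.Generator | int | None = None,
) -> TemporalResult:
    """Per-timepoint decoding with nested fivefold C selection.

    For each sample, features are the component amplitudes at that
    sample; inner cross-validation on the training pool selects the C
    maximizing mean inner AUC (ties favour the smallest C, i.e. the
    strongest regularization), the classifier is refitted on the full
    pool and scored on the three test sets.
    """
    ytr = np.asarray(train.labels).astype(int)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(rng)
    n_times = train.data.shape[2]
    auc = {cond: np.empty(n_times) for cond in tests}
    selected = np.empty(n_times)
    for ti in range(n_times):
        X = train.data[:, :, ti]
        seed = int(rng.integers(2**31))
        C = _select_C(X, ytr, C_grid, inner_folds, seed)
        selected[ti] = C
        mu, sd = _zscore_train(X)
        model = fit_logistic((X - mu) / sd, ytr, C=C)
        for cond, es in tests.items():
            Xt = es.data[:, :, ti]
            yt = np.asarray(es.labels).astype(int)
            auc[cond][ti] = compute_auc(model.decision_function((Xt - mu) / sd), yt)
    return TemporalResult(auc=auc, times=train.times.copy(), selected_C=selected)
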