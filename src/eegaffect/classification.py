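"""RBF-SVM training, grid search, and the two cross-validation schemes.

Subject-dependent accuracy comes from leave-one-trial-out cross-validation
(LOTO-CV): within one subject, each trial in turn is the test set and the
remaining trials the training set.  Subject-independent accuracy comes from
leave-one-subject-out cross-validation (LOSO-CV): each subject in turn is
held out against a model trained on all other subjects.  In both schemes the
(C, gamma) pair is chosen by exhaustive grid search maximizing the unweighted
mean of fold accuracies, with ties broken toward the smallest C then the
smallest gamma (prefer the simpler model, deterministically).

Normalization discipline: LOTO fits the per-feature min/max on the training
trials only and applies it (clipped) to the held-out trial, so no test
information reaches training; a ``normalization="pooled"`` mode fitting on
all of the subject's rows is available for comparison.  LOSO normalizes each
subject self-contained on its own min/max, matching the per-participant
scaling of the protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import FeatureMatrix, apply_norm_params, minmax_normalize, normalize_per_subject

__all__ = [
    "SVMConfig",
    "Fold",
    "CVResult",
    "train_svm",
    "loto_cv",
    "loso_cv",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

PERSISTENCE_VERSION = 1


def _pow2(lo: int, hi: int, step: int = 2) -> tuple[float, ...]:
    return tuple(float(2.0 ** e) for e in range(lo, hi + 1, step))


@dataclass(frozen=True)
class SVMConfig:
    """Gaussian-kernel SVM hyperparameters and the search grid.

    Default grid: C in 2^-5..2^15 and gamma in 2^-15..2^3, exponent step 2
    (the standard coarse libsvm-style grid).
    """

    C: float = 1.0
    gamma: float = 2.0 ** -5
    c_grid: tuple[float, ...] = field(default_factory=lambda: _pow2(-5, 15))
    gamma_grid: tuple[float, ...] = field(default_factory=lambda: _pow2(-15, 3))

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("grid must be non-empty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("grid values must be positive")

    def grid(self) -> list[tuple[float, float]]:
        """(C, gamma) combinations sorted so first-wins = smallest C, gamma."""
        return [(c, g) for c in sorted(self.c_grid) for g in sorted(self.gamma_grid)]


@dataclass(frozen=True)
class Fold:
    held_out_id: int
    accuracy: float
    n_test: int


@dataclass
class CVResult:
    scheme: Literal["LOTO", "LOSO"]
    folds: list[Fold]
    mean_accuracy: float
    chosen_params: tuple[float, float]  # (C, gamma)
    grid_means: dict[tuple[float, float], float] = field(default_factory=dict)

    def fold_accuracy(self, held_out_id: int) -> float:
        for f in self.folds:
            if f.held_out_id == held_out_id:
                return f.accuracy
        raise KeyError(held_out_id)


def train_svm(X: np.ndarray, y: Sequence[str], C: float, gamma: float) -> SVC:
    """Fit a Gaussian-kernel SVM; deterministic for fixed inputs."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = SVC(kernel="rbf", C=C, gamma=gamma, cache_size=500)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def _grid_search(
    splits: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]],
    cfg: SVMConfig,
) -> tuple[tuple[float, float], list[Fold], float, dict]:
    """Exhaustive grid search over precomputed (Xtr, ytr, Xte, yte, id) splits."""
    best: tuple[float, float] | None = None
    best_mean = -np.inf
    best_folds: list[Fold] = []
    grid_means: dict[tuple[float, float], float] = {}
    for C, gamma in cfg.grid():
        folds = []
        for Xtr, ytr, Xte, yte, held_id in splits:
            model = train_svm(Xtr, ytr, C, gamma)
            acc = float(np.mean(model.predict(Xte) == yte))
            folds.append(Fold(held_out_id=held_id, accuracy=acc, n_test=len(yte)))
        mean = float(np.mean([f.accuracy for f in folds]))
        grid_means[(C, gamma)] = mean
        if mean > best_mean:  # strict: first (smallest C, gamma) wins ties
            best_mean = mean
            best = (C, gamma)
            best_folds = folds
    assert best is not None
    return best, best_folds, best_mean, grid_means


def loto_cv(
    fm: FeatureMatrix,
    cfg: SVMConfig | None = None,
    normalization: Literal["train", "pooled", "none"] = "train",
) -> CVResult:
    """Leave-one-trial-out CV for a single subject's unnormalized features."""
    cfg = cfg or SVMConfig()
    subjects = np.unique(fm.subject_ids)
    if len(subjects) != 1:
        raise ValueError("loto_cv expects the rows of exactly one subject")
    trials = np.unique(fm.trial_ids)
    if len(trials) < 2:
        raise ValueError("LOTO-CV needs at least 2 trials")

    splits = []
    for t in trials:
        te_mask = fm.trial_ids == t
        tr_mask = ~te_mask
        if normalization == "train":
            norm = minmax_normalize(fm, fit_rows=tr_mask)
        elif normalization == "pooled":
            norm = minmax_normalize(fm)
        else:
            norm = fm
        splits.append(
            (norm.values[tr_mask], fm.labels[tr_mask],
             norm.values[te_mask], fm.labels[te_mask], int(t))
        )
    chosen, folds, mean, grid_means = _grid_search(splits, cfg)
    logger.debug("LOTO subject %s: best %s mean=%.3f", subjects[0], chosen, mean)
    return CVResult("LOTO", folds, mean, chosen, grid_means)


def loso_cv(fm: FeatureMatrix, cfg: SVMConfig | None = None) -> CVResult:
    """Leave-one-subject-out CV over an unnormalized multi-subject matrix.

    Every subject (training and held-out alike) is min-max scaled on its own
    rows before the folds are formed, so the held-out subject's scaling is
    self-contained and no cross-subject statistics leak.
    """
    cfg = cfg or SVMConfig()
    subjects = np.unique(fm.subject_ids)
    if len(subjects) < 2:
        raise ValueError("LOSO-CV needs at least 2 subjects")
    norm = fm if fm.normalized else normalize_per_subject(fm)

    splits = []
    for s in subjects:
        te_mask = fm.subject_ids == s
        tr_mask = ~te_mask
        splits.append(
            (norm.values[tr_mask], fm.labels[tr_mask],
             norm.values[te_mask], fm.labels[te_mask], int(s))
        )
    chosen, folds, mean, grid_means = _grid_search(splits, cfg)
    logger.debug("LOSO: best %s mean=%.3f", chosen, mean)
    return CVResult("LOSO", folds, mean, chosen, grid_means)


# ---------------------------------------------------------------------------
# Model persistence (consumed by the real-time detector)
# ---------------------------------------------------------------------------

def save_model(
    path: str | Path,
    model: SVC,
    norm_params,
    channels: Sequence[str],
    bands: Sequence[str],
    sampling_rate: float,
    wavelet: str = "db4",
    metadata: dict | None = None,
) -> None:
    payload = {
        "format_version": PERSISTENCE_VERSION,
        "model": model,
        "norm_params": norm_params,
        "channels": list(channels),
        "bands": list(bands),
        "sampling_rate": float(sampling_rate),
        "wavelet": wavelet,
        "metadata": metadata or {},
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> dict:
    payload = joblib.load(path)
    if payload.get("format_version") != PERSISTENCE_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('format_version')!r}"
        )
    return payload
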