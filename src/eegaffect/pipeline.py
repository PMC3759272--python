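"""End-to-end conveniences tying the stages together.

``cohort_features`` is the canonical offline path: notch -> baseline ->
1 s epoching -> wavelet band powers, concatenated over all recordings of a
cohort into one unnormalized feature matrix.  ``train_detector_model`` runs
the subject-dependent model-selection loop and packages the final model the
streaming detector loads.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .classification import SVMConfig, loto_cv, save_model, train_svm
from .evaluation import _concat_features
from .features import (
    BandScheme,
    FeatureMatrix,
    assemble_features,
    dyadic_scheme,
    minmax_normalize,
)
from .preprocessing import epoch, notch_filter, remove_baseline
from .synthetic import EEGRecording

__all__ = ["preprocess", "cohort_features", "train_detector_model"]


def preprocess(
    rec: EEGRecording,
    mains_freqs: Sequence[float] = (50.0, 60.0),
    baseline: bool = True,
) -> EEGRecording:
    out = notch_filter(rec, mains_freqs)
    return remove_baseline(out) if baseline else out


def cohort_features(
    recordings: Sequence[EEGRecording],
    window_length: float = 1.0,
    channels: Sequence[str] | None = None,
    scheme: BandScheme | None = None,
    wavelet: str = "db4",
    mains_freqs: Sequence[float] = (50.0, 60.0),
) -> FeatureMatrix:
    """Preprocess and featurize every trial of a cohort (unnormalized)."""
    parts = []
    for rec in recordings:
        clean = preprocess(rec, mains_freqs)
        ws = epoch(clean, window_length)
        parts.append(
            assemble_features(ws, scheme=scheme, wavelet=wavelet, channels=channels)
        )
    return _concat_features(parts)


def train_detector_model(
    fm: FeatureMatrix,
    subject_id: int,
    path: str | Path,
    cfg: SVMConfig | None = None,
    channels: Sequence[str] | None = None,
    sampling_rate: float = 128.0,
    wavelet: str = "db4",
) -> dict:
    """Select (C, gamma) by LOTO-CV on one subject, then fit on all its rows.

    The final model is trained on the subject's full feature set normalized
    by its own min/max; those norm parameters are stored with the model so
    the online path reuses them (with clipping).  Returns a summary dict.
    """
    sub = fm.subset_rows(fm.subject_ids == subject_id)
    if channels is not None:
        sub = sub.select_channels(channels)
    cv = loto_cv(sub, cfg)
    C, gamma = cv.chosen_params
    norm = minmax_normalize(sub)
    model = train_svm(norm.values, norm.labels, C, gamma)
    bands = list(dict.fromkeys(b for _, b in sub.columns))
    save_model(
        path,
        model,
        norm.norm_params,
        channels=list(dict.fromkeys(ch for ch, _ in sub.columns)),
        bands=bands,
        sampling_rate=sampling_rate,
        wavelet=wavelet,
        metadata={
            "subject_id": int(subject_id),
            "loto_mean_accuracy": cv.mean_accuracy,
            "C": C,
            "gamma": gamma,
        },
    )
    return {
        "subject_id": int(subject_id),
        "C": C,
        "gamma": gamma,
        "loto_mean_accuracy": cv.mean_accuracy,
        "path": str(path),
    }
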