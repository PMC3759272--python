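"""Cohort-level experiments: model comparison, ablations, significance.

Four experiments over a cohort's features, mirroring the study design:

* subject-dependent (LOTO) vs subject-independent (LOSO) accuracy, with and
  without a configurable excluded-subject set;
* channel-pair ablation over the 7 homologous left/right pairs (10 features
  per condition);
* frequency-band ablation over the 5 bands (14 features per condition);
* stimulus-duration ablation (first 30 s vs last 30 s vs full 60 s).

Per-subject accuracies are paired across conditions, so differences are
tested with a two-sided paired t-test across subjects (alpha = 0.05); an
optional Holm correction is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import CVResult, SVMConfig, loso_cv, loto_cv
from .features import FeatureMatrix
from .preprocessing import epoch
from .synthetic import EEGRecording

__all__ = [
    "HOMOLOGOUS_PAIRS",
    "Condition",
    "AblationReport",
    "paired_test",
    "per_subject_loto",
    "channel_pair_ablation",
    "band_ablation",
    "duration_ablation",
    "model_comparison",
]

logger = logging.getLogger(__name__)

#: The 7 homologous (left, right) electrode pairs of the 14-channel montage.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"), ("FC5", "FC6"),
    ("P7", "P8"), ("T7", "T8"), ("O1", "O2"),
)


@dataclass
class Condition:
    name: str
    per_subject: dict[int, float]  # subject_id -> accuracy in [0, 1]
    mean_accuracy: float
    chosen_params: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass
class AblationReport:
    axis: str  # channel_pair | band | duration | model_type
    conditions: list[Condition]
    comparisons: list[tuple[str, str, float, str]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def ranking(self) -> list[str]:
        """Condition names sorted by decreasing mean accuracy."""
        return [
            c.name
            for c in sorted(self.conditions, key=lambda c: -c.mean_accuracy)
        ]

    def to_frame(self) -> pd.DataFrame:
        subjects = sorted({s for c in self.conditions for s in c.per_subject})
        rows = []
        for c in self.conditions:
            row = {"condition": c.name, "mean_accuracy": c.mean_accuracy}
            row.update({f"subject_{s}": c.per_subject.get(s) for s in subjects})
            rows.append(row)
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.comparisons, columns=["condition_a", "condition_b", "p_value", "test"]
        )

    def plot(self, ax=None, title: str | None = None):
        """Bar chart of condition means (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.conditions) + 2, 4))
        names = [c.name for c in self.conditions]
        means = [100 * c.mean_accuracy for c in self.conditions]
        ax.bar(names, means)
        ax.set_ylabel("accuracy (%)")
        ax.set_ylim(0, 100)
        ax.axhline(50, ls="--", c="grey", lw=1)
        if title:
            ax.set_title(title)
        return ax


def paired_test(acc_a: Sequence[float], acc_b: Sequence[float]) -> float:
    """Two-sided paired t-test across subjects.

    Identical vectors return p = 1 by convention (no evidence of any
    difference).  A nonzero but perfectly constant difference has zero
    variance, leaving the t statistic undefined; that limit is reported as
    p = 0 (the difference is observed without exception).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired accuracy vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    if np.std(diff) == 0:
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def per_subject_loto(
    fm: FeatureMatrix, cfg: SVMConfig | None = None
) -> dict[int, CVResult]:
    """LOTO-CV for every subject in the matrix; features must be unnormalized."""
    return {
        int(s): loto_cv(fm.subset_rows(fm.subject_ids == s), cfg)
        for s in np.unique(fm.subject_ids)
    }


def _condition_from_results(name: str, results: dict[int, CVResult]) -> Condition:
    per_subject = {s: r.mean_accuracy for s, r in results.items()}
    return Condition(
        name=name,
        per_subject=per_subject,
        mean_accuracy=float(np.mean(list(per_subject.values()))),
        chosen_params={s: r.chosen_params for s, r in results.items()},
    )


def _pairwise_comparisons(conditions: list[Condition]) -> list[tuple[str, str, float, str]]:
    out = []
    for a, b in combinations(conditions, 2):
        subjects = sorted(set(a.per_subject) & set(b.per_subject))
        p = paired_test(
            [a.per_subject[s] for s in subjects],
            [b.per_subject[s] for s in subjects],
        )
        out.append((a.name, b.name, p, "paired t-test"))
    return out


def channel_pair_ablation(
    fm: FeatureMatrix,
    pairs: Sequence[tuple[str, str]] = HOMOLOGOUS_PAIRS,
    cfg: SVMConfig | None = None,
) -> AblationReport:
    """Subject-dependent (LOTO) accuracy per homologous channel pair.

    Each condition uses only that pair's 10 features (2 channels x 5 bands).
    Conditions are reported sorted by decreasing mean accuracy.
    """
    conditions = []
    for left, right in pairs:
        sub = fm.select_channels([left, right])
        results = per_subject_loto(sub, cfg)
        conditions.append(_condition_from_results(f"{left}-{right}", results))
        logger.info("pair %s-%s: mean=%.3f", left, right, conditions[-1].mean_accuracy)
    conditions.sort(key=lambda c: -c.mean_accuracy)
    return AblationReport(
        axis="channel_pair",
        conditions=conditions,
        comparisons=_pairwise_comparisons(conditions),
    )


def band_ablation(
    fm: FeatureMatrix,
    bands: Sequence[str] | None = None,
    cfg: SVMConfig | None = None,
) -> AblationReport:
    """Subject-dependent (LOTO) accuracy per frequency band (14 features)."""
    bands = list(bands) if bands is not None else sorted({b for _, b in fm.columns})
    known = {b for _, b in fm.columns}
    missing = set(bands) - known
    if missing:
        raise KeyError(f"unknown bands {sorted(missing)}")
    conditions = []
    for band in bands:
        sub = fm.select_bands([band])
        results = per_subject_loto(sub, cfg)
        conditions.append(_condition_from_results(band, results))
        logger.info("band %s: mean=%.3f", band, conditions[-1].mean_accuracy)
    return AblationReport(
        axis="band",
        conditions=conditions,
        comparisons=_pairwise_comparisons(conditions),
    )


def duration_ablation(
    recordings: Sequence[EEGRecording],
    cfg: SVMConfig | None = None,
    window_length: float = 1.0,
    assemble_kwargs: dict | None = None,
) -> AblationReport:
    """Accuracy using the first half, last half, or all of each stimulus.

    Re-epochs the recordings per portion, so it consumes recordings rather
    than a precomputed feature matrix.  Includes pairwise paired t-tests.
    """
    from .features import assemble_features  # local import to avoid cycle noise

    assemble_kwargs = assemble_kwargs or {}
    conditions = []
    for portion, name in (
        ("first_half", "first_half"),
        ("second_half", "second_half"),
        ("full", "full"),
    ):
        rows = []
        for rec in recordings:
            ws = epoch(rec, window_length, portion=portion)
            rows.append(assemble_features(ws, **assemble_kwargs))
        fm = _concat_features(rows)
        results = per_subject_loto(fm, cfg)
        conditions.append(_condition_from_results(name, results))
    return AblationReport(
        axis="duration",
        conditions=conditions,
        comparisons=_pairwise_comparisons(conditions),
    )


def _concat_features(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    first = parts[0]
    if any(p.columns != first.columns for p in parts[1:]):
        raise ValueError("feature matrices have mismatched columns")
    from dataclasses import replace

    return replace(
        first,
        values=np.vstack([p.values for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        trial_ids=np.concatenate([p.trial_ids for p in parts]),
        window_indices=np.concatenate([p.window_indices for p in parts]),
    )


def model_comparison(
    fm: FeatureMatrix,
    cfg: SVMConfig | None = None,
    loso_cfg: SVMConfig | None = None,
    exclude: Sequence[int] = (),
) -> AblationReport:
    """Subject-dependent (LOTO) vs subject-independent (LOSO) accuracy.

    Per subject: LOTO mean accuracy and the LOSO fold accuracy where that
    subject was held out.  ``extras`` carries the cohort means recomputed
    after dropping ``exclude`` (e.g. the attenuated-response subjects).
    """
    subjects = sorted(int(s) for s in np.unique(fm.subject_ids))
    exclude = sorted(set(int(s) for s in exclude))
    if set(exclude) >= set(subjects):
        raise ValueError("cannot exclude every subject")

    loto_results = per_subject_loto(fm, cfg)
    loso_result = loso_cv(fm, loso_cfg or cfg)

    loto_cond = _condition_from_results("subject_dependent_LOTO", loto_results)
    loso_per_subject = {
        int(f.held_out_id): f.accuracy for f in loso_result.folds
    }
    loso_cond = Condition(
        name="subject_independent_LOSO",
        per_subject=loso_per_subject,
        mean_accuracy=loso_result.mean_accuracy,
        chosen_params={s: loso_result.chosen_params for s in subjects},
    )
    conditions = [loto_cond, loso_cond]
    extras: dict = {}
    if exclude:
        keep = [s for s in subjects if s not in exclude]
        extras["excluded_subjects"] = exclude
        extras["loto_mean_excluding"] = float(
            np.mean([loto_cond.per_subject[s] for s in keep])
        )
        extras["loso_mean_excluding"] = float(
            np.mean([loso_per_subject[s] for s in keep])
        )
    return AblationReport(
        axis="model_type",
        conditions=conditions,
        comparisons=_pairwise_comparisons(conditions),
        extras=extras,
    )
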