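"""Confusion-based metrics, per-fold aggregation and Wilcoxon comparisons.

Glaucoma is the positive class throughout: sensitivity is the fraction of
glaucoma subjects flagged, specificity the fraction of controls cleared.
Balanced accuracy — the mean of the two — is the headline metric because the
cohorts are imbalanced (122 controls vs 105 patients).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"
GLAUCOMA = "glaucoma"

#: Mean per-fold confusion counts reported for the clinical SLO experiments
#: with the task-specific architecture (single model and the four ensemble
#: combination rules, at k = 5 and k = 10), together with the published
#: sensitivity/specificity columns.  Kept as a worked example: re-deriving
#: sen/spe from the mean counts must reproduce the printed values to three
#: decimals.
REFERENCE_CONFUSION_MEANS = pd.DataFrame(
    [
        (5, "single cnn model", 21.6, 2.8, 1.6, 19.4, 0.924, 0.885),
        (5, "mv regular", 22.7, 1.7, 0.0, 21.0, 1.000, 0.930),
        (5, "mv weighted", 22.6, 1.8, 1.4, 19.6, 0.933, 0.926),
        (5, "sa regular", 22.4, 2.0, 1.2, 19.8, 0.943, 0.918),
        (5, "sa weighted", 22.4, 2.0, 1.2, 19.8, 0.943, 0.918),
        (10, "single cnn model", 11.0, 1.2, 1.2, 9.3, 0.886, 0.902),
        (10, "mv regular", 11.2, 1.0, 0.6, 9.9, 0.943, 0.918),
        (10, "mv weighted", 11.2, 1.0, 0.6, 9.9, 0.943, 0.918),
        (10, "sa regular", 11.2, 1.0, 0.6, 9.9, 0.943, 0.918),
        (10, "sa weighted", 11.2, 1.0, 0.6, 9.9, 0.943, 0.918),
    ],
    columns=["k", "method", "tn", "fp", "fn", "tp", "sen", "spe"],
)


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (e.g. no positives in the fold)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """tn/fp/fn/tp counts; fractional values allowed (means over folds)."""

    tn: float
    fp: float
    fn: float
    tp: float

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}={getattr(self, name)}")
        if self.tn + self.fp + self.fn + self.tp <= 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> float:
        return self.tn + self.fp + self.fn + self.tp


def confusion(y_true, y_pred, positive_class: str = GLAUCOMA) -> ConfusionCounts:
    """Count tn/fp/fn/tp with ``positive_class`` as the positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.shape}, y_pred has {y_pred.shape}"
        )
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tp=int(np.sum(pos_t & pos_p)),
    )


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """sensitivity = tp/(tp+fn), specificity = tn/(tn+fp)."""
    if counts.tp + counts.fn <= 0:
        raise UndefinedMetricError("sensitivity undefined: tp + fn == 0")
    if counts.tn + counts.fp <= 0:
        raise UndefinedMetricError("specificity undefined: tn + fp == 0")
    return counts.tp / (counts.tp + counts.fn), counts.tn / (counts.tn + counts.fp)


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (sensitivity + specificity) / 2.0


def balanced_accuracy_from_counts(counts: ConfusionCounts) -> float:
    sen, spe = sensitivity_specificity(counts)
    return balanced_accuracy(sen, spe)


@dataclass
class EvalResult:
    """Per-fold confusion counts and derived metrics for one model."""

    model_id: str
    fold_counts: list[ConfusionCounts]

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([sensitivity_specificity(c)[0] for c in self.fold_counts])

    @property
    def specificities(self) -> np.ndarray:
        return np.array([sensitivity_specificity(c)[1] for c in self.fold_counts])

    @property
    def balanced_accuracies(self) -> np.ndarray:
        return (self.sensitivities + self.specificities) / 2.0

    def summary(self) -> dict[str, float]:
        ba = self.balanced_accuracies
        return {
            "model": self.model_id,
            "balanced_accuracy_mean": float(np.mean(ba)),
            "balanced_accuracy_sd": float(np.std(ba, ddof=1)) if len(ba) > 1 else 0.0,
            "sensitivity_mean": float(np.mean(self.sensitivities)),
            "specificity_mean": float(np.mean(self.specificities)),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.fold_counts):
            sen, spe = sensitivity_specificity(c)
            rows.append(
                {
                    "fold": i,
                    "model": self.model_id,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tp": c.tp,
                    "sen": sen,
                    "spe": spe,
                    "balanced_accuracy": (sen + spe) / 2.0,
                }
            )
        return pd.DataFrame(rows)


def wilcoxon_compare(
    results_a,
    results_b,
    alpha: float = 0.05,
    zero_method: str = "wilcox",
) -> tuple[float, bool]:
    """Two-sided paired Wilcoxon signed-rank test on per-fold scores.

    Exact null distribution for n <= 25 (no ties/zeros); all-zero difference
    sequences — identical per-fold scores — are reported as p = 1, not
    significant, rather than an error, since that outcome carries no evidence
    of a difference.  ``zero_method`` follows scipy ("wilcox" drops zero
    differences, "pratt" keeps them in the ranking).
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score sequences must have equal length")
    if a.size < 5:
        raise ValueError(f"need >= 5 paired scores, got {a.size}")
    d = a - b
    if np.all(d == 0):
        return 1.0, False
    res = stats.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided",
                         method="auto")
    p = float(res.pvalue)
    return p, bool(p < alpha)


@dataclass
class ComparisonMatrix:
    """Pairwise Wilcoxon p-values plus the papers-style 'better model' flags."""

    model_ids: list[str]
    p_values: np.ndarray  # symmetric, NaN diagonal
    better: dict[tuple[str, str], str]  # (a, b) -> id of significantly better model
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.model_ids, columns=self.model_ids)

    def annotation_for(self, model_id: str) -> list[str]:
        """Ids of models significantly better than ``model_id`` (footnote style)."""
        out = []
        for (a, b), winner in self.better.items():
            if model_id in (a, b) and winner != model_id:
                out.append(winner)
        return sorted(set(out))


def build_comparison_matrix(all_results: list[EvalResult], alpha: float = 0.05) -> ComparisonMatrix:
    """Pairwise Wilcoxon over per-fold balanced accuracies.

    For each significant pair the model with the higher mean is recorded,
    mirroring the "number below the metric" convention of the result tables.
    """
    if len(all_results) < 2:
        raise ValueError("need at least 2 result sets to compare")
    n_folds = {len(r.fold_counts) for r in all_results}
    if len(n_folds) != 1:
        raise ValueError(f"mismatched fold counts: {sorted(n_folds)}")
    ids = [r.model_id for r in all_results]
    m = len(ids)
    p = np.full((m, m), np.nan)
    better: dict[tuple[str, str], str] = {}
    for i, j in itertools.combinations(range(m), 2):
        ba_i = all_results[i].balanced_accuracies
        ba_j = all_results[j].balanced_accuracies
        pv, sig = wilcoxon_compare(ba_i, ba_j, alpha=alpha)
        p[i, j] = p[j, i] = pv
        if sig:
            winner = ids[i] if ba_i.mean() > ba_j.mean() else ids[j]
            better[(ids[i], ids[j])] = winner
    return ComparisonMatrix(model_ids=ids, p_values=p, better=better, alpha=alpha)
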