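"""Performance metrics for classification, regression and fold-error analysis.

Classification is scored from the raw confusion matrix: Cohen's Kappa
(chance-corrected agreement), per-class sensitivity/specificity via
one-vs-rest, and balanced accuracy as their mean.  Regression is scored by
the coefficient of determination r² = 1 − SS_res/SS_tot (which may be
negative) and RMSE, in either linear or log10 space.

Pharmacokinetic predictions are additionally judged by fold error,
``max(pred/obs, obs/pred)`` on the linear clearance scale; "within k-fold"
is boundary-inclusive (fold error ≤ k).  The range-split report scores the
high and low clearance ranges separately, split at the mean intermediate-
type clearance (1.02 mL/min/kg), by observed and by predicted value —
the high predicted range is the reliable operating regime of the two-step
system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import ttest_rel
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .pk_core import DEFAULT_CONSTANTS, PhysiologyConstants

__all__ = [
    "EvaluationReport",
    "confusion_stats",
    "regression_stats",
    "fold_errors",
    "fold_error_fraction",
    "range_split_report",
    "paired_split_comparison",
]


@dataclass
class EvaluationReport:
    """Metrics for one model on one partition; absent metrics are None."""

    task: str
    n: int
    kappa: float | None = None
    balanced_accuracy: dict | None = None
    sensitivity: dict | None = None
    specificity: dict | None = None
    r2: float | None = None
    rmse: float | None = None
    fold_error_2x: float | None = None
    fold_error_3x: float | None = None
    range_split: dict | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kappa is not None and not (-1 - 1e-9 <= self.kappa <= 1 + 1e-9):
            raise ValueError(f"kappa out of [-1, 1]: {self.kappa}")
        for name in ("fold_error_2x", "fold_error_3x"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name} must be a percentage in [0, 100]: {v}")
        if (
            self.fold_error_2x is not None
            and self.fold_error_3x is not None
            and self.fold_error_2x > self.fold_error_3x + 1e-9
        ):
            raise ValueError("fraction within 2-fold cannot exceed fraction within 3-fold")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def confusion_stats(predicted, truth) -> dict:
    """Kappa, balanced accuracy, sensitivity and specificity from a confusion matrix.

    Multiclass Kappa uses the full confusion matrix; sensitivity,
    specificity and balanced accuracy are computed per class one-vs-rest.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    classes = sorted(set(np.unique(truth)) | set(np.unique(predicted)), key=str)
    if len(set(np.unique(truth))) < 2:
        raise ValueError("need at least 2 classes present in the truth labels")
    cm = confusion_matrix(truth, predicted, labels=classes)
    kappa = float(cohen_kappa_score(truth, predicted, labels=classes))
    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    balanced: dict[str, float] = {}
    total = cm.sum()
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        key = str(cls)
        sensitivity[key] = float(sens)
        specificity[key] = float(spec)
        balanced[key] = float((sens + spec) / 2)
    return {
        "kappa": kappa,
        "balanced_accuracy": balanced,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "confusion_matrix": cm.tolist(),
        "classes": [str(c) for c in classes],
    }


def regression_stats(predicted, observed, space: str = "linear") -> dict:
    """r² (coefficient of determination, may be negative) and RMSE.

    With ``space="log10"`` both vectors must be strictly positive and the
    statistics are computed on their base-10 logarithms.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("length mismatch between predicted and observed")
    if len(observed) < 2:
        raise ValueError("need at least 2 observations")
    if space == "log10":
        if not ((predicted > 0).all() and (observed > 0).all()):
            raise ValueError("log10 space requires strictly positive values")
        predicted, observed = np.log10(predicted), np.log10(observed)
    elif space != "linear":
        raise ValueError(f"unknown space {space!r}")
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if ss_tot == 0:
        return {"r2": None, "rmse": rmse, "flag": "zero-variance observed: r2 undefined"}
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse}


def fold_errors(predicted, observed, ids: Sequence[str] | None = None) -> np.ndarray:
    """Per-compound fold error max(pred/obs, obs/pred) on the linear scale."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    bad = np.where((predicted <= 0) | (observed <= 0))[0]
    if len(bad):
        names = [ids[i] for i in bad] if ids is not None else bad.tolist()
        raise ValueError(f"nonpositive clearance value(s) for: {names}")
    return np.maximum(predicted / observed, observed / predicted)


def fold_error_fraction(
    predicted, observed, k: float, ids: Sequence[str] | None = None
) -> float:
    """Percent of compounds whose fold error is within k-fold (inclusive)."""
    if not (k > 1):
        raise ValueError(f"k must exceed 1, got {k!r}")
    fe = fold_errors(predicted, observed, ids)
    if len(fe) == 0:
        raise ValueError("no compounds to score")
    return float(np.mean(fe <= k) * 100.0)


def range_split_report(
    predicted,
    observed,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Fold-error statistics split into high and low clearance ranges.

    Two partitions are scored, one splitting on the observed and one on the
    predicted CLr, both at ``constants.clr_range_cut`` (strictly greater is
    high).  Each sub-report carries n and the within-2-fold / within-3-fold
    percentages; an empty side is flagged empty rather than an error.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    fold_errors(predicted, observed)  # validates positivity
    cut = constants.clr_range_cut
    out: dict = {"cut": cut}
    for split_name, basis in (("by_observed", observed), ("by_predicted", predicted)):
        sides = {}
        for side, mask in (("high", basis > cut), ("low", ~(basis > cut))):
            if not mask.any():
                sides[side] = {"n": 0, "empty": True}
                continue
            sides[side] = {
                "n": int(mask.sum()),
                "within_2fold_pct": fold_error_fraction(
                    predicted[mask], observed[mask], 2.0
                ),
                "within_3fold_pct": fold_error_fraction(
                    predicted[mask], observed[mask], 3.0
                ),
            }
        out[split_name] = sides
    return out


def paired_split_comparison(series_a, series_b) -> dict:
    """Two-sided paired t-test over matched random splits.

    ``series_a`` and ``series_b`` are per-split values of one metric for two
    configurations, paired by split seed.  Degenerate difference series
    (zero variance, including identical series) are flagged with an
    undefined p-value rather than raising.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must be paired (equal lengths)")
    if len(a) < 3:
        raise ValueError("need at least 3 paired splits")
    diff = b - a
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        return {
            "mean_difference": mean_diff,
            "p_value": None,
            "flag": "zero variance of paired differences: p undefined",
        }
    stat = ttest_rel(b, a)
    return {"mean_difference": mean_diff, "p_value": float(stat.pvalue)}
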