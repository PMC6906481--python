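"""Training-set-only feature-reduction cascade.

Three stages, fit on the training partition and then applied to any other
partition purely by feature name:

1. near-zero-variance filter — drops quasi-constant columns by the
   frequency-ratio / percent-unique rule;
2. pairwise-correlation pruning — greedily removes one member of every
   feature pair whose absolute Pearson correlation exceeds a cutoff
   (0.90 by default);
3. Boruta — all-relevant selection that compares each real feature's
   random-forest importance against permuted "shadow" copies and keeps
   features whose cumulative hit count is binomially significant.

Boruta is implemented here in full (shadow augmentation, max-shadow hit
rule, two-sided binomial tests with Bonferroni correction) with the
scikit-learn random forest as the importance engine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .featurize import DescriptorMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionReport",
    "near_zero_variance_filter",
    "correlation_filter",
    "boruta_select",
    "SelectionCascade",
]


@dataclass
class SelectionReport:
    """Outcome of the reduction cascade on one training matrix."""

    removed_nzv: list[str] = field(default_factory=list)
    removed_correlated: list[str] = field(default_factory=list)
    boruta_confirmed: list[str] = field(default_factory=list)
    boruta_tentative: list[str] = field(default_factory=list)
    boruta_rejected: list[str] = field(default_factory=list)
    n_iterations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [
            set(self.removed_nzv),
            set(self.removed_correlated),
            set(self.boruta_confirmed),
            set(self.boruta_tentative),
            set(self.boruta_rejected),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("selection report name sets must be disjoint")

    @property
    def selected(self) -> list[str]:
        """Final feature list: Boruta-confirmed only (tentative excluded)."""
        return list(self.boruta_confirmed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionReport":
        return cls(**json.loads(Path(path).read_text()))


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, DescriptorMatrix) else matrix


def _same_container(matrix, frame: pd.DataFrame):
    if isinstance(matrix, DescriptorMatrix):
        return matrix.select(list(frame.columns))
    return frame


def near_zero_variance_filter(
    matrix,
    freq_ratio_cut: float = 19.0,
    unique_percent_cut: float = 10.0,
):
    """Remove quasi-constant features.

    A feature is removed iff the ratio of the most-common to the
    second-most-common value count exceeds ``freq_ratio_cut`` AND the
    percentage of distinct values is below ``unique_percent_cut``; constant
    columns are always removed.  Returns ``(filtered, removed_names)``.
    """
    frame = _as_frame(matrix)
    if len(frame) < 2:
        raise ValueError("need at least 2 rows for the near-zero-variance filter")
    removed: list[str] = []
    n = len(frame)
    for col in frame.columns:
        counts = frame[col].value_counts(dropna=False)
        n_unique = len(counts)
        if n_unique <= 1:
            removed.append(col)
            continue
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        unique_percent = n_unique / n * 100.0
        if freq_ratio > freq_ratio_cut and unique_percent < unique_percent_cut:
            removed.append(col)
    kept = [c for c in frame.columns if c not in set(removed)]
    return _same_container(matrix, frame[kept]), removed


def correlation_filter(matrix, cutoff: float = 0.90):
    """Greedy pruning of highly correlated feature pairs.

    While any off-diagonal absolute Pearson correlation exceeds ``cutoff``,
    the member of the worst pair with the larger mean absolute correlation
    to the remaining features is removed.  The output is guaranteed to
    contain no pair above the cutoff.  Zero-variance columns are an error —
    run the near-zero-variance filter first.
    """
    frame = _as_frame(matrix)
    if len(frame) < 3:
        raise ValueError("need at least 3 rows for the correlation filter")
    variances = frame.var(axis=0, ddof=0)
    zero_var = variances[variances == 0].index.tolist()
    if zero_var:
        raise ValueError(
            f"zero-variance columns present (run the NZV filter first): {zero_var}"
        )
    corr = frame.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    names = list(frame.columns)
    alive = np.ones(len(names), dtype=bool)
    removed: list[str] = []
    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        block = corr[np.ix_(sub, sub)]
        flat = np.argmax(block)
        i, j = np.unravel_index(flat, block.shape)
        if block[i, j] <= cutoff:
            break
        gi, gj = sub[i], sub[j]
        # Mean |r| of each member against all other remaining features.
        mean_i = block[i].sum() / (len(sub) - 1)
        mean_j = block[j].sum() / (len(sub) - 1)
        drop = gi if mean_i >= mean_j else gj
        alive[drop] = False
        removed.append(names[drop])
    kept = [names[k] for k in range(len(names)) if alive[k]]
    return _same_container(matrix, frame[kept]), removed


def _forest(task: str, seed: int, n_trees: int):
    common = dict(
        n_estimators=n_trees,
        random_state=seed,
        n_jobs=1,
        max_features="sqrt",
    )
    if task == "classification":
        return RandomForestClassifier(**common)
    if task == "regression":
        return RandomForestRegressor(**common)
    raise ValueError(f"unknown task {task!r}")


def boruta_select(
    matrix,
    target,
    task: str = "classification",
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int = 0,
    n_trees: int = 500,
    removed_nzv: Sequence[str] = (),
    removed_correlated: Sequence[str] = (),
) -> SelectionReport:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends an independently permuted (shadow) copy of every
    undecided feature, fits a random forest, and records a *hit* for each
    real feature whose impurity importance exceeds the maximum shadow
    importance.  After every iteration each undecided feature's cumulative
    hit count is tested two-sided against Binomial(iterations, 1/2) with
    Bonferroni correction over the full feature set: significantly many
    hits confirms it, significantly few rejects it.  Stops at ``max_iter``
    or when nothing remains tentative.  A constant target rejects all
    features.  Deterministic for a fixed seed.

    On pure-noise data most features are rejected quickly, but the single
    strongest *spurious* in-sample correlate can be confirmed: at n = 200
    with 20 features the expected best spurious |r| is about 0.2, which is
    a borderline-significant association of the fixed sample, and the
    max-shadow hit rule cannot distinguish it from weak real signal.  This
    is a property of the shadow-comparison scheme itself, not of this
    implementation.
    """
    frame = _as_frame(matrix)
    y = np.asarray(target)
    if len(y) != len(frame):
        raise ValueError(f"target length {len(y)} != row count {len(frame)}")
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 features")
    X = frame.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix; drop failed features first")
    if task == "regression" and not np.isfinite(y.astype(float)).all():
        raise ValueError("non-finite values in target")

    names = list(frame.columns)
    p = len(names)
    if len(np.unique(y)) <= 1:
        # Degenerate target: nothing can be relevant.
        return SelectionReport(
            removed_nzv=list(removed_nzv),
            removed_correlated=list(removed_correlated),
            boruta_rejected=list(names),
            n_iterations=0,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    undecided = np.ones(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    confirmed = np.zeros(p, dtype=bool)
    rejected = np.zeros(p, dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        active = np.where(undecided | confirmed)[0]
        if not undecided.any():
            n_iter -= 1
            break
        Xa = X[:, active]
        # Pad to at least 5 shadow columns: with very few active features,
        # "beat the max shadow" would otherwise degenerate to a coin flip
        # and sequential testing would eventually confirm noise.
        shadow_src = Xa
        while shadow_src.shape[1] < 5:
            shadow_src = np.hstack([shadow_src, Xa])
        shadow = shadow_src.copy()
        for col in range(shadow.shape[1]):
            shadow[:, col] = shadow[rng.permutation(len(shadow)), col]
        forest = _forest(task, int(rng.integers(2**31 - 1)), n_trees)
        forest.fit(np.hstack([Xa, shadow]), y)
        imp = forest.feature_importances_
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active):].max()
        for k, feat in enumerate(active):
            if undecided[feat] and real_imp[k] > shadow_max:
                hits[feat] += 1
        # Binomial decisions on cumulative hit counts; constant Bonferroni
        # over the full feature set (a correction shrinking with rejections
        # would grow more liberal exactly when borderline features remain).
        for feat in np.where(undecided)[0]:
            pval = binomtest(int(hits[feat]), n_iter, 0.5).pvalue * p
            if pval < alpha:
                if hits[feat] > n_iter / 2:
                    confirmed[feat] = True
                else:
                    rejected[feat] = True
                undecided[feat] = False
        if not undecided.any():
            break

    report = SelectionReport(
        removed_nzv=list(removed_nzv),
        removed_correlated=list(removed_correlated),
        boruta_confirmed=[names[i] for i in range(p) if confirmed[i]],
        boruta_tentative=[names[i] for i in range(p) if undecided[i]],
        boruta_rejected=[names[i] for i in range(p) if rejected[i]],
        n_iterations=n_iter,
        seed=seed,
    )
    logger.info(
        "boruta: %d confirmed / %d tentative / %d rejected in %d iterations",
        len(report.boruta_confirmed),
        len(report.boruta_tentative),
        len(report.boruta_rejected),
        n_iter,
    )
    return report


class SelectionCascade:
    """Fit the full NZV → correlation → Boruta cascade on a training matrix
    and apply it elsewhere by feature name only (no re-fitting).

    ``use_boruta=False`` stops after the first two filters, in which case the
    selected set is simply every survivor.
    """

    def __init__(
        self,
        freq_ratio_cut: float = 19.0,
        unique_percent_cut: float = 10.0,
        corr_cutoff: float = 0.90,
        use_boruta: bool = True,
        alpha: float = 0.01,
        max_iter: int = 100,
        n_trees: int = 500,
        seed: int = 0,
    ):
        self.freq_ratio_cut = freq_ratio_cut
        self.unique_percent_cut = unique_percent_cut
        self.corr_cutoff = corr_cutoff
        self.use_boruta = use_boruta
        self.alpha = alpha
        self.max_iter = max_iter
        self.n_trees = n_trees
        self.seed = seed
        self.report: SelectionReport | None = None
        self.selected_: list[str] | None = None

    def fit(self, matrix, target=None, task: str = "classification") -> "SelectionCascade":
        filtered, removed_nzv = near_zero_variance_filter(
            matrix, self.freq_ratio_cut, self.unique_percent_cut
        )
        filtered, removed_corr = correlation_filter(filtered, self.corr_cutoff)
        if self.use_boruta:
            if target is None:
                raise ValueError("Boruta requires a target")
            self.report = boruta_select(
                filtered,
                target,
                task=task,
                alpha=self.alpha,
                max_iter=self.max_iter,
                seed=self.seed,
                n_trees=self.n_trees,
                removed_nzv=removed_nzv,
                removed_correlated=removed_corr,
            )
            self.selected_ = self.report.selected
        else:
            frame = _as_frame(filtered)
            self.report = SelectionReport(
                removed_nzv=removed_nzv,
                removed_correlated=removed_corr,
                boruta_confirmed=list(frame.columns),
                seed=self.seed,
            )
            self.selected_ = list(frame.columns)
        return self

    def transform(self, matrix):
        """Select the fitted feature set by name from any matrix."""
        if self.selected_ is None:
            raise RuntimeError("cascade is not fitted")
        if isinstance(matrix, DescriptorMatrix):
            return matrix.select(self.selected_)
        return matrix[self.selected_]
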