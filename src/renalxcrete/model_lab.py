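"""Learner-agnostic training harness.

Four learner families — random forest, radial-kernel SVM, a single-hidden-
layer neural network, and partial least squares — each tuned by a 10-fold
cross-validated grid search with four candidate values per tuning parameter.
Cross-validation selects on accuracy (classification) or RMSE (regression);
the final choice among trained families uses test-set Cohen's Kappa or r².

Renal-clearance regression is done on log10(CLr): clearances span orders of
magnitude and errors are multiplicative, so the squared loss is taken in log
space and predictions are back-transformed exactly once at prediction time.

The scikit-learn estimators stand behind each family; PLS classification
(PLS-DA: one-hot targets, argmax decoding) is a thin wrapper because
scikit-learn ships only the regressor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, cohen_kappa_score, mean_squared_error
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = [
    "FAMILIES",
    "LearnerSpec",
    "TrainedModel",
    "default_grid",
    "cv_grid_search",
    "select_best_model",
    "save_model",
    "load_model",
]

FAMILIES = ("random_forest", "svm_radial", "neural_net", "pls")
_SCALED_FAMILIES = {"svm_radial", "neural_net", "pls"}


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis: PLS regression on one-hot labels, argmax decode."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.classes_, encoded = np.unique(y, return_inverse=True)
        Y = np.eye(len(self.classes_))[encoded]
        if len(self.classes_) == 2:
            Y = Y[:, [1]]
        n_comp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=n_comp)
        self.pls_.fit(X, Y)
        return self

    def predict(self, X):
        scores = self.pls_.predict(X)
        if scores.shape[1] == 1:
            idx = (scores[:, 0] >= 0.5).astype(int)
        else:
            idx = np.argmax(scores, axis=1)
        return self.classes_[idx]


@dataclass(frozen=True)
class LearnerSpec:
    """One learner family with its task, tuning grid and multiclass strategy.

    The grid maps each tuned hyperparameter to exactly four candidate
    values.  ``native`` multiclass handling is the random forest's;
    one-vs-one is the radial SVM's pairwise scheme and one-vs-rest the
    neural net's (softmax/multinomial) scheme.
    """

    family: str
    task: str  # binary | multiclass | regression
    grid: tuple = ()  # tuple of (param, (v1, v2, v3, v4))
    multiclass_strategy: str = "native"
    seed: int = 0
    rf_trees: int = 500

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.task not in ("binary", "multiclass", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        for param, values in self.grid:
            if len(values) != 4:
                raise ValueError(
                    f"grid for {param!r} must hold exactly 4 values, got {len(values)}"
                )
        if self.task == "multiclass":
            allowed = {
                "random_forest": "native",
                "svm_radial": "one_vs_one",
                "neural_net": "one_vs_rest",
                "pls": "one_vs_rest",
            }
            if self.multiclass_strategy != allowed[self.family]:
                raise ValueError(
                    f"{self.family} multiclass strategy must be {allowed[self.family]!r}"
                )

    @property
    def grid_dict(self) -> dict:
        return {param: list(values) for param, values in self.grid}


@dataclass
class TrainedModel:
    """A fitted learner plus everything needed to reproduce and apply it."""

    spec: LearnerSpec
    selected_features: list[str]
    estimator: object
    cv_results: list[dict] = field(default_factory=list)
    chosen_hyperparams: dict = field(default_factory=dict)
    target_transform: str = "identity"  # identity | log10

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict on a feature table; applies the inverse target transform
        exactly once for log10-trained regressors."""
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks model features: {missing}")
        values = X[self.selected_features].to_numpy(dtype=float)
        raw = self.estimator.predict(values)
        if self.target_transform == "log10":
            return np.power(10.0, np.asarray(raw, dtype=float))
        return np.asarray(raw)

    def manifest(self) -> dict:
        return {
            "family": self.spec.family,
            "task": self.spec.task,
            "grid": self.spec.grid_dict,
            "multiclass_strategy": self.spec.multiclass_strategy,
            "seed": self.spec.seed,
            "rf_trees": self.spec.rf_trees,
            "selected_features": self.selected_features,
            "chosen_hyperparams": self.chosen_hyperparams,
            "target_transform": self.target_transform,
            "cv_results": self.cv_results,
        }


def _median_heuristic_gamma(X: np.ndarray, seed: int) -> float:
    """RBF kernel width from the median pairwise distance of (a sample of) X."""
    rng = np.random.default_rng(seed)
    n = len(X)
    idx = rng.permutation(n)[: min(n, 200)]
    sub = X[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    if med <= 0:
        return 1.0 / max(1, X.shape[1])
    return 1.0 / med


def default_grid(family: str, task: str, n_features: int) -> tuple:
    """Four candidate values for the family's primary tuning parameter.

    Random forest tunes the features-per-split count over four points from
    √p to p/2 (trees fixed at 500); the radial SVM tunes cost over
    {0.25, 0.5, 1, 2} with the kernel width set by the median-distance
    heuristic; the neural net tunes four (hidden size, weight decay)
    points; PLS tunes the number of components over {1, 2, 3, 4}.
    """
    if family == "random_forest":
        lo = max(1, int(round(np.sqrt(n_features))))
        hi = max(lo + 1, n_features // 2)
        mtry = sorted(set(np.linspace(lo, hi, 4).round().astype(int).tolist()))
        while len(mtry) < 4:  # tiny p: pad upward within bounds
            mtry.append(min(n_features, mtry[-1] + 1))
        return (("max_features", tuple(int(v) for v in mtry[:4])),)
    if family == "svm_radial":
        return (("C", (0.25, 0.5, 1.0, 2.0)),)
    if family == "neural_net":
        return (("hidden_decay", ((3, 1e-3), (5, 1e-3), (9, 1e-2), (15, 1e-2))),)
    if family == "pls":
        cap = max(1, min(n_features, 4))
        comps = tuple(min(c, cap) for c in (1, 2, 3, 4))
        return (("n_components", comps),)
    raise ValueError(f"unknown family {family!r}")


def _build_estimator(spec: LearnerSpec, params: dict, X: np.ndarray):
    is_regression = spec.task == "regression"
    seed = spec.seed
    if spec.family == "random_forest":
        cls = RandomForestRegressor if is_regression else RandomForestClassifier
        max_features = min(int(params["max_features"]), X.shape[1])
        return cls(
            n_estimators=spec.rf_trees,
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "svm_radial":
        gamma = _median_heuristic_gamma(X, seed)
        if is_regression:
            core = SVR(kernel="rbf", C=params["C"], gamma=gamma)
        else:
            # SVC is inherently pairwise (one-vs-one) for >2 classes.
            core = SVC(kernel="rbf", C=params["C"], gamma=gamma, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("model", core)])
    if spec.family == "neural_net":
        hidden, decay = params["hidden_decay"]
        cls = MLPRegressor if is_regression else MLPClassifier
        core = cls(
            hidden_layer_sizes=(int(hidden),),
            alpha=float(decay),
            max_iter=2000,
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("model", core)])
    if spec.family == "pls":
        if is_regression:
            core = PLSRegression(n_components=int(params["n_components"]))
        else:
            core = PLSDAClassifier(n_components=int(params["n_components"]))
        return Pipeline([("scale", StandardScaler()), ("model", core)])
    raise ValueError(f"unknown family {spec.family!r}")


def _grid_points(grid: tuple) -> list[dict]:
    points = [{}]
    for param, values in grid:
        points = [{**pt, param: v} for v in values for pt in points]
    return points


def cv_grid_search(
    spec: LearnerSpec,
    matrix: pd.DataFrame,
    target,
    k: int = 10,
    target_transform: str = "identity",
) -> TrainedModel:
    """Tune one learner by k-fold cross-validated grid search and refit.

    The fold partition is fixed by the spec's seed (stratified for
    classification).  For each grid point the mean held-out metric —
    accuracy for classification, RMSE for regression (in transformed space)
    — is recorded; the best point is refit on the full training matrix.
    Ties go to the earlier grid point.
    """
    if isinstance(matrix, pd.DataFrame):
        features = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        raise TypeError("matrix must be a pandas DataFrame of features")
    y = np.asarray(target)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing/non-finite values")
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")

    is_regression = spec.task == "regression"
    if is_regression:
        y = y.astype(float)
        if target_transform == "log10":
            if not (y > 0).all():
                raise ValueError("log10 target transform requires positive targets")
            y_fit = np.log10(y)
        else:
            y_fit = y
    else:
        y_fit = y
        if target_transform != "identity":
            raise ValueError("target transforms apply to regression only")

    grid = spec.grid or default_grid(spec.family, spec.task, X.shape[1])
    spec = LearnerSpec(
        family=spec.family,
        task=spec.task,
        grid=grid,
        multiclass_strategy=spec.multiclass_strategy,
        seed=spec.seed,
        rf_trees=spec.rf_trees,
    )

    if is_regression:
        folds = list(KFold(n_splits=k, shuffle=True, random_state=spec.seed).split(X))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
        try:
            folds = list(splitter.split(X, y_fit))
        except ValueError as exc:
            raise ValueError(f"stratified {k}-fold split failed: {exc}") from exc
        fold_classes = [set(np.unique(y_fit[tr])) for tr, _ in folds]
        if any(c != set(np.unique(y_fit)) for c in fold_classes):
            raise ValueError("a class is absent from some training fold")

    cv_results = []
    for params in _grid_points(grid):
        scores = []
        for train_idx, test_idx in folds:
            est = _build_estimator(spec, params, X[train_idx])
            est.fit(X[train_idx], y_fit[train_idx])
            pred = est.predict(X[test_idx])
            if is_regression:
                scores.append(
                    float(np.sqrt(mean_squared_error(y_fit[test_idx], pred)))
                )
            else:
                scores.append(float(accuracy_score(y_fit[test_idx], pred)))
        cv_results.append(
            {"params": params, "mean_metric": float(np.mean(scores))}
        )

    if is_regression:
        best_i = int(np.argmin([r["mean_metric"] for r in cv_results]))
    else:
        best_i = int(np.argmax([r["mean_metric"] for r in cv_results]))
    best_params = cv_results[best_i]["params"]
    final = _build_estimator(spec, best_params, X)
    final.fit(X, y_fit)
    return TrainedModel(
        spec=spec,
        selected_features=features,
        estimator=final,
        cv_results=cv_results,
        chosen_hyperparams=best_params,
        target_transform=target_transform if is_regression else "identity",
    )


def select_best_model(
    candidates: Sequence[TrainedModel],
    test_matrix: pd.DataFrame,
    test_target,
):
    """Choose the best family on the held-out test set.

    Classification maximizes test Cohen's Kappa; regression maximizes test
    r².  Ties break on lower test RMSE, then on family order as listed in
    :data:`FAMILIES`.  Returns ``(best, per_model_report)``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    tasks = {c.spec.task for c in candidates}
    if len(tasks) > 1:
        raise ValueError(f"candidates mix tasks: {tasks}")
    task = tasks.pop()
    y = np.asarray(test_target)
    report = []
    keys = []
    for model in candidates:
        pred = model.predict(test_matrix)
        if task == "regression":
            obs = y.astype(float)
            if model.target_transform == "log10":
                lp, lo = np.log10(pred), np.log10(obs)
            else:
                lp, lo = pred, obs
            ss_res = float(np.sum((lo - lp) ** 2))
            ss_tot = float(np.sum((lo - lo.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
            rmse = float(np.sqrt(np.mean((lo - lp) ** 2)))
            report.append(
                {"family": model.spec.family, "r2": r2, "rmse": rmse}
            )
            keys.append((-r2, rmse, FAMILIES.index(model.spec.family)))
        else:
            kappa = float(cohen_kappa_score(y, pred))
            # 0/1 error rate doubles as the RMSE tie-break for labels.
            err = float(np.mean(pred != y))
            rmse = float(np.sqrt(err))
            report.append(
                {"family": model.spec.family, "kappa": kappa, "rmse": rmse}
            )
            keys.append((-kappa, rmse, FAMILIES.index(model.spec.family)))
    best = candidates[min(range(len(keys)), key=keys.__getitem__)]
    return best, report


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist as a directory: JSON manifest + opaque fitted blob."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.json").write_text(
        json.dumps(model.manifest(), indent=2, sort_keys=True)
    )
    joblib.dump(model.estimator, directory / "estimator.joblib")


def load_model(directory: str | Path) -> TrainedModel:
    """Load a persisted model, rebuilding the spec from its manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = LearnerSpec(
        family=manifest["family"],
        task=manifest["task"],
        grid=tuple(
            (param, tuple(tuple(v) if isinstance(v, list) else v for v in values))
            for param, values in manifest["grid"].items()
        ),
        multiclass_strategy=manifest["multiclass_strategy"],
        seed=manifest["seed"],
        rf_trees=manifest.get("rf_trees", 500),
    )
    return TrainedModel(
        spec=spec,
        selected_features=manifest["selected_features"],
        estimator=joblib.load(directory / "estimator.joblib"),
        cv_results=manifest["cv_results"],
        chosen_hyperparams=manifest["chosen_hyperparams"],
        target_transform=manifest["target_transform"],
    )
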