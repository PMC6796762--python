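"""Grid-searched base classifiers for single-encoding models.

Two classifier families carry the final predictor:

* **SVM** with an RBF kernel, tuned over the exponential grid
  C in {2^-5, 2^-3, ..., 2^15} and gamma in {2^-15, ..., 2^-5}.
  Inputs are min-max scaled with parameters learned on training data
  (most encodings are already in [0, 1]; NUM sits in [0.25, 1]).
  Probabilities come from the standard sigmoid (Platt) calibration
  fitted during the final refit.
* **ERT** (extremely randomized trees), tuned over the number of trees
  (50..2000 step 25), the number of candidate split features mtry
  (1..15) and the minimum samples to split a node nsplit (1..12).
  Tree inputs are left unscaled.  nsplit=1 and mtry above the feature
  count are clamped to the nearest feasible value and duplicate
  effective settings are searched once.

Random forest and gradient-boosted trees are available behind the same
interface as experimental plug-ins with small library-default grids.

Grid search maximises mean accuracy over stratified k-fold
cross-validation; the winner is refit on all training data.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "TrainedSingleModel",
    "svm_spec",
    "ert_spec",
    "rf_spec",
    "xgb_spec",
    "svm_spec_small",
    "ert_spec_small",
    "build_estimator",
    "grid_search",
    "tune_and_fit",
    "fit_model",
    "predict_probability",
]

#: Full exponent ranges for the SVM grid.
SVM_C_EXPONENTS = tuple(range(-5, 16, 2))  # 11 values
SVM_GAMMA_EXPONENTS = tuple(range(-15, -4))  # 11 values


@dataclass
class ClassifierSpec:
    """A classifier family plus its hyperparameter search grid."""

    kind: str  # SVM | ERT | RF | XGB
    param_grid: dict[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def combinations(self) -> list[dict]:
        keys = list(self.param_grid)
        return [
            dict(zip(keys, vals))
            for vals in product(*(self.param_grid[k] for k in keys))
        ]


def svm_spec(seed: int = 0) -> ClassifierSpec:
    """RBF-SVM with the full 11x11 exponential C/gamma grid."""
    return ClassifierSpec(
        kind="SVM",
        param_grid={
            "C": tuple(2.0**e for e in SVM_C_EXPONENTS),
            "gamma": tuple(2.0**e for e in SVM_GAMMA_EXPONENTS),
        },
        seed=seed,
    )


def svm_spec_small(seed: int = 0) -> ClassifierSpec:
    """5x5 sub-grid of the full SVM grid for time-constrained runs."""
    return ClassifierSpec(
        kind="SVM",
        param_grid={
            "C": tuple(2.0**e for e in (-5, -1, 3, 7, 11)),
            "gamma": tuple(2.0**e for e in (-15, -11, -9, -7, -5)),
        },
        seed=seed,
    )


def ert_spec(seed: int = 0) -> ClassifierSpec:
    """Extremely randomized trees with the full ntree/mtry/nsplit grid."""
    return ClassifierSpec(
        kind="ERT",
        param_grid={
            "ntree": tuple(range(50, 2001, 25)),
            "mtry": tuple(range(1, 16)),
            "nsplit": tuple(range(1, 13)),
        },
        seed=seed,
    )


def ert_spec_small(seed: int = 0) -> ClassifierSpec:
    """Reduced ERT sub-grid (8 combinations) for time-constrained runs."""
    return ClassifierSpec(
        kind="ERT",
        param_grid={
            "ntree": (50, 100),
            "mtry": (2, 8),
            "nsplit": (2, 6),
        },
        seed=seed,
    )


def rf_spec(seed: int = 0) -> ClassifierSpec:
    """Random forest plug-in (experimental; library-default grid)."""
    return ClassifierSpec(
        kind="RF",
        param_grid={"ntree": (100, 300), "nsplit": (2, 5)},
        seed=seed,
    )


def xgb_spec(seed: int = 0) -> ClassifierSpec:
    """Gradient-boosted trees plug-in (experimental; needs xgboost)."""
    return ClassifierSpec(
        kind="XGB",
        param_grid={"n_estimators": (100, 300), "max_depth": (3, 6)},
        seed=seed,
    )


def _effective_params(kind: str, params: dict, n_features: int) -> dict:
    """Clamp grid points to values the implementation can honour."""
    out = dict(params)
    if kind in ("ERT", "RF"):
        if "nsplit" in out:
            out["nsplit"] = max(2, int(out["nsplit"]))
        if "mtry" in out:
            out["mtry"] = min(int(out["mtry"]), n_features)
    return out


def build_estimator(
    kind: str, params: dict, seed: int = 0, probability: bool = False
):
    """Construct an unfitted sklearn-style estimator for one grid point.

    SVM estimators embed their min-max scaler in a pipeline so scaling
    parameters are always learned from the data the model is fit on.
    """
    if kind == "SVM":
        svc = SVC(
            kernel="rbf",
            C=params["C"],
            gamma=params["gamma"],
            random_state=seed,
        )
        if probability:
            # sigmoid (Platt) calibration on cross-validated decision values
            est = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
        else:
            est = svc
        return Pipeline([("scale", MinMaxScaler()), ("svc", est)])
    if kind == "ERT":
        return ExtraTreesClassifier(
            n_estimators=int(params["ntree"]),
            max_features=int(params["mtry"]),
            min_samples_split=int(params["nsplit"]),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=int(params.get("ntree", 100)),
            min_samples_split=int(params.get("nsplit", 2)),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "XGB":
        from xgboost import XGBClassifier  # optional dependency

        return XGBClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            max_depth=int(params.get("max_depth", 6)),
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise KeyError(f"unknown classifier kind {kind!r}")


FoldData = Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]


def grid_search(spec: ClassifierSpec, fold_data: FoldData) -> tuple[dict, float]:
    """Exhaustive grid search over pre-materialised CV folds.

    ``fold_data`` is a sequence of ``(X_train, y_train, X_val, y_val)``
    tuples; supplying features per fold (rather than slicing one matrix)
    lets reference-dependent encodings such as KNN stay fold-internal.
    Returns the winning parameter dict and its mean CV accuracy; ties go
    to the first grid point in deterministic enumeration order.
    """
    if not fold_data:
        raise ValueError("no folds supplied")
    n_features = fold_data[0][0].shape[1]
    best_params: Optional[dict] = None
    best_acc = -1.0
    seen: set[tuple] = set()
    for params in spec.combinations():
        eff = _effective_params(spec.kind, params, n_features)
        key = tuple(sorted(eff.items()))
        if key in seen:
            continue
        seen.add(key)
        correct = 0
        total = 0
        for Xtr, ytr, Xva, yva in fold_data:
            est = build_estimator(spec.kind, eff, seed=spec.seed, probability=False)
            est.fit(Xtr, ytr)
            correct += int((est.predict(Xva) == yva).sum())
            total += len(yva)
        acc = correct / total
        if acc > best_acc:
            best_acc = acc
            best_params = eff
    assert best_params is not None
    return best_params, best_acc


@dataclass
class TrainedSingleModel:
    """A fitted single-encoding model with its tuned hyperparameters.

    ``selected_features`` indexes into the full encoding matrix; callers
    always pass the full matrix and the model slices internally, so a
    model and its feature subset travel together.
    """

    kind: str
    params: dict
    encoding_name: str
    estimator: object  # fitted; SVM models are (scaler, SVC) pipelines
    selected_features: Optional[np.ndarray] = None
    cv_accuracy: Optional[float] = None
    seed: int = 0

    @property
    def input_dim(self) -> Optional[int]:
        from .encoders import ENCODING_DIMS

        return ENCODING_DIMS.get(self.encoding_name)

    def _slice(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        expected = self.input_dim
        if expected is not None and X.shape[1] != expected:
            raise ValueError(
                f"{self.encoding_name} model expects {expected} columns, "
                f"got {X.shape[1]}"
            )
        if self.selected_features is not None:
            X = X[:, self.selected_features]
        return X


def fit_model(
    spec: ClassifierSpec,
    params: dict,
    mat,
    y: Sequence[int],
    encoding_name: str = "",
    selected_features: Optional[np.ndarray] = None,
    cv_accuracy: Optional[float] = None,
) -> TrainedSingleModel:
    """Refit one grid point on the full training data (with probabilities)."""
    X = getattr(mat, "values", mat)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if selected_features is not None:
        selected_features = np.asarray(selected_features, dtype=int)
        X = X[:, selected_features]
    eff = _effective_params(spec.kind, params, X.shape[1])
    est = build_estimator(spec.kind, eff, seed=spec.seed, probability=True)
    est.fit(X, y)
    return TrainedSingleModel(
        kind=spec.kind,
        params=eff,
        encoding_name=encoding_name or getattr(mat, "encoding_name", ""),
        estimator=est,
        selected_features=selected_features,
        cv_accuracy=cv_accuracy,
        seed=spec.seed,
    )


def tune_and_fit(
    spec: ClassifierSpec,
    mat,
    y: Sequence[int],
    folds: int = 10,
    fold_indices: Optional[Sequence[tuple[np.ndarray, np.ndarray]]] = None,
) -> TrainedSingleModel:
    """Grid-search hyperparameters by stratified CV accuracy, then refit.

    The chosen parameters always lie inside the declared grid (modulo
    the documented feasibility clamps).
    """
    X = getattr(mat, "values", mat)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if fold_indices is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        fold_indices = list(skf.split(X, y))
    fold_data = [(X[tr], y[tr], X[va], y[va]) for tr, va in fold_indices]
    params, acc = grid_search(spec, fold_data)
    return fit_model(
        spec,
        params,
        X,
        y,
        encoding_name=getattr(mat, "encoding_name", ""),
        cv_accuracy=acc,
    )


def predict_probability(model: TrainedSingleModel, mat) -> np.ndarray:
    """Positive-class probability per record, in [0, 1].

    Expects the full encoding matrix for the model's encoding; the
    model applies its own feature subset and (for SVM) scaling.
    """
    X = model._slice(getattr(mat, "values", mat))
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    return proba[:, classes.index(1)]
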