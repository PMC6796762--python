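"""Two-step feature optimisation: F-score ranking + sequential forward search.

Step 1 ranks every feature by its univariate F-score, the squared
deviations of the class means from the overall mean divided by the sum
of the within-class sample variances,

    F(i) = [ (x+_i - x_i)^2 + (x-_i - x_i)^2 ]
           / [ s2+_i + s2-_i ]            (sample variances, ddof=1)

Larger is better: a feature whose class means sit far apart relative to
its within-class spread separates the classes well on its own.  Note
this is the feature-selection F-score, not the F1 classification metric.

Step 2 walks prefixes of the ranked list (starting from the top two
features and growing), scoring each prefix by stratified k-fold
cross-validated accuracy of a frozen classifier, and keeps the smallest
prefix attaining the maximum accuracy.  The full feature set is always
among the evaluated prefixes, so the selected subset can never score
below it on the same folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RankedFeatures",
    "SfsResult",
    "f_score",
    "f_score_columns",
    "rank_features",
    "sequential_forward_search",
]


@dataclass
class RankedFeatures:
    """Feature indices sorted by descending F-score (ties by index)."""

    order: np.ndarray  # permutation of column indices
    scores: np.ndarray  # F-score per original column

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        ranked = self.scores[self.order]
        if np.any(np.diff(ranked) > 1e-12):
            raise ValueError("order does not sort scores non-increasingly")


@dataclass
class SfsResult:
    """Outcome of the sequential forward search over ranked prefixes."""

    selected: np.ndarray  # the chosen prefix of the ranked order
    k: int
    curve_sizes: np.ndarray  # evaluated prefix sizes
    curve_accuracy: np.ndarray  # CV accuracy per evaluated size

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.tolist(),
            "k": int(self.k),
            "curve_sizes": self.curve_sizes.tolist(),
            "curve_accuracy": self.curve_accuracy.tolist(),
        }


def f_score(feature_values: Sequence[float], labels: Sequence[int]) -> float:
    """F-score of a single feature (scalar convenience wrapper)."""
    x = np.asarray(feature_values, dtype=float).reshape(-1, 1)
    return float(f_score_columns(x, np.asarray(labels, dtype=int))[0])


def f_score_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised per-column F-scores.

    Columns that are constant within both classes have a zero
    denominator; their score is defined as 0 (with a warning), matching
    the convention that an uninformative constant ranks last.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = X[y == 1]
    neg = X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 records to compute variances")
    mean_all = X.mean(axis=0)
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    num = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    zero = den == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} feature(s) constant within both classes; "
            "F-score set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros(X.shape[1], dtype=float)
    nz = ~zero
    out[nz] = num[nz] / den[nz]
    return out


def rank_features(mat, y: Sequence[int]) -> RankedFeatures:
    """Rank features of a matrix by descending F-score (stable ties)."""
    X = getattr(mat, "values", mat)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("matrix rows and labels are misaligned")
    scores = f_score_columns(X, y)
    order = np.argsort(-scores, kind="stable")
    return RankedFeatures(order=order, scores=scores)


def sequential_forward_search(
    mat,
    y: Sequence[int],
    ranked: RankedFeatures,
    estimator_factory: Callable[[], object],
    folds: int = 10,
    seed: int = 0,
    step: int = 1,
    min_k: int = 2,
    fold_indices: Optional[Sequence[tuple[np.ndarray, np.ndarray]]] = None,
) -> SfsResult:
    """Pick the CV-accuracy-maximising prefix of the ranked feature list.

    Prefix sizes ``min_k, min_k+step, ...`` are evaluated, always
    including the full dimension; the same stratified folds (fixed by
    ``seed``) are used for every prefix so the accuracy curve is
    comparable across sizes.  Ties go to the smallest prefix.

    ``estimator_factory`` must return a fresh unfitted classifier with
    frozen hyperparameters; it is cloned per fold.  ``step`` trades
    curve resolution for runtime on wide encodings.
    """
    X = getattr(mat, "values", mat)
    y = np.asarray(y, dtype=int)
    dim = X.shape[1]
    if len(ranked.order) != dim:
        raise ValueError("ranking does not cover all feature columns")
    sizes = list(range(min_k, dim + 1, step))
    if sizes[-1] != dim:
        sizes.append(dim)
    if fold_indices is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_indices = list(skf.split(X, y))
    accs = np.empty(len(sizes), dtype=float)
    for s_idx, k in enumerate(sizes):
        cols = ranked.order[:k]
        correct = 0
        total = 0
        for tr, va in fold_indices:
            est = clone(estimator_factory())
            try:
                est.fit(X[np.ix_(tr, cols)], y[tr])
            except Exception as exc:
                raise RuntimeError(f"learner failed at prefix size {k}: {exc}") from exc
            pred = est.predict(X[np.ix_(va, cols)])
            correct += int((pred == y[va]).sum())
            total += len(va)
        accs[s_idx] = correct / total
    best = int(np.argmax(accs))  # argmax takes the first (smallest) maximiser
    k = sizes[best]
    return SfsResult(
        selected=ranked.order[:k].copy(),
        k=k,
        curve_sizes=np.asarray(sizes),
        curve_accuracy=accs,
    )
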