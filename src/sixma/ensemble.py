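"""Two-layer ensemble: weighted per-encoding fusion, then classifier average.

Layer 1 combines, within each classifier family (SVM, ERT), the
positive-class probabilities of the five single-encoding models as a
weighted sum.  The weights are non-negative multiples of a grid step
summing to exactly one; the grid of all such simplex points is searched
exhaustively for the weight vector maximising accuracy at the 0.5
threshold on *out-of-fold* probabilities, so the weights never see a
prediction made by a model trained on the same record.

Layer 2 averages the layer-1 scores of the classifier families with
equal weights and thresholds the mean at 0.5 (a score equal to the
threshold is called positive; the boundary convention is documented and
tested).

:func:`train_ensemble` runs the whole training protocol: per encoding
and classifier it tunes hyperparameters by CV accuracy, optimises the
feature subset by F-score ranking + sequential forward search (the
7-dimensional KNN encoding is exempt), refits on all training data, and
finally fits the layer-1 weights on out-of-fold probabilities from the
same stratified folds.  The KNN encoding is rebuilt fold-internally
with self-exclusion throughout, which keeps its features leakage-free.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import joblib
import numpy as np

from . import __version__ as _pkg_version
from .encoders import (
    DEFAULT_ENCODINGS,
    KnnReference,
    build_knn_reference,
    encode_dataset,
    encode_knn_batch,
    encode_records,
)
from .learners import (
    ClassifierSpec,
    TrainedSingleModel,
    build_estimator,
    ert_spec,
    fit_model,
    grid_search,
    predict_probability,
    rf_spec,
    svm_spec,
    xgb_spec,
)
from .selection import SfsResult, rank_features, sequential_forward_search
from .seqio import LabeledDataset, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LayerOneWeights",
    "PipelineConfig",
    "ClassifierEnsemble",
    "TrainedEnsemble",
    "enumerate_simplex_weights",
    "layer1_combine",
    "optimize_layer1_weights",
    "layer2_combine",
    "classify",
    "train_ensemble",
    "save_ensemble",
    "load_ensemble",
]

_SPEC_FACTORIES = {"SVM": svm_spec, "ERT": ert_spec, "RF": rf_spec, "XGB": xgb_spec}

ARCHIVE_SCHEMA_VERSION = 1


@dataclass
class LayerOneWeights:
    """Per-encoding fusion weights: simplex point on a fixed grid."""

    weights: np.ndarray
    grid_step: float = 0.1
    encodings: tuple[str, ...] = DEFAULT_ENCODINGS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to one")


def enumerate_simplex_weights(n_streams: int = 5, grid_step: float = 0.1) -> np.ndarray:
    """All weight vectors whose entries are multiples of the step and sum to 1.

    Enumerated in lexicographic order of the underlying integer
    compositions, which fixes the tie-break of the weight search.
    """
    m = round(1.0 / grid_step)
    if abs(m * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1 exactly (e.g. 0.1, 0.05)")

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first, *rest)

    pts = np.array(list(compositions(m, n_streams)), dtype=float) / m
    return pts


def _stack_streams(prob_streams: Sequence[np.ndarray]) -> np.ndarray:
    lengths = {len(p) for p in prob_streams}
    if len(lengths) != 1:
        raise ValueError(f"probability streams are misaligned: lengths {sorted(lengths)}")
    return np.stack([np.asarray(p, dtype=float) for p in prob_streams])


def layer1_combine(prob_streams: Sequence[np.ndarray], w: LayerOneWeights) -> np.ndarray:
    """Weighted sum of per-encoding probability streams."""
    P = _stack_streams(prob_streams)
    if P.shape[0] != len(w.weights):
        raise ValueError("number of streams does not match number of weights")
    return w.weights @ P


def optimize_layer1_weights(
    prob_streams: Sequence[np.ndarray],
    labels: Sequence[int],
    grid_step: float = 0.1,
    threshold: float = 0.5,
    encodings: tuple[str, ...] = DEFAULT_ENCODINGS,
) -> LayerOneWeights:
    """Exhaustive simplex grid search for the accuracy-maximising weights.

    Must be fed out-of-fold probabilities; resubstitution probabilities
    would reward overfit streams.  Ties are broken by enumeration order
    (first lexicographic maximiser), making the result deterministic.
    """
    P = _stack_streams(prob_streams)
    y = np.asarray(labels, dtype=int)
    if P.shape[1] != len(y):
        raise ValueError("streams and labels are misaligned")
    grid = enumerate_simplex_weights(P.shape[0], grid_step)
    scores = grid @ P  # (n_grid, n_records)
    acc = ((scores >= threshold).astype(int) == y).mean(axis=1)
    best = int(np.argmax(acc))
    return LayerOneWeights(weights=grid[best], grid_step=grid_step, encodings=encodings)


def layer2_combine(scores: Sequence[np.ndarray]) -> np.ndarray:
    """Equal-weight mean of the classifier-family scores."""
    return _stack_streams(scores).mean(axis=0)


def classify(final_probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label positive iff probability >= threshold (boundary is positive)."""
    return (np.asarray(final_probs, dtype=float) >= threshold).astype(int)


@dataclass
class PipelineConfig:
    """Everything needed to train the two-layer predictor.

    Defaults reproduce the selected architecture: five encodings, SVM +
    ERT classifier families, 10 stratified folds, weight grid step 0.1
    and decision threshold 0.5, with the full hyperparameter grids and
    per-dimension sequential forward search.  ``specs`` may override the
    search grid per classifier (e.g. the reduced sub-grids from
    :mod:`sixma.learners` for time-constrained runs); ``sfs_step``
    coarsens the prefix-size stride of the forward search.
    """

    encodings: tuple[str, ...] = DEFAULT_ENCODINGS
    classifiers: tuple[str, ...] = ("SVM", "ERT")
    folds: int = 10
    seed: int = 0
    grid_step: float = 0.1
    threshold: float = 0.5
    sfs: bool = True
    sfs_step: int = 1
    specs: dict = field(default_factory=dict)  # kind -> ClassifierSpec

    def spec_for(self, kind: str) -> ClassifierSpec:
        if kind in self.specs:
            spec = self.specs[kind]
            return replace(spec, seed=self.seed) if spec.seed != self.seed else spec
        return _SPEC_FACTORIES[kind](seed=self.seed)


@dataclass
class ClassifierEnsemble:
    """Layer-1 bundle: five fitted models plus their fusion weights."""

    kind: str
    models: dict  # encoding name -> TrainedSingleModel
    weights: LayerOneWeights
    sfs_results: dict = field(default_factory=dict)  # encoding -> SfsResult


@dataclass
class TrainedEnsemble:
    """The full two-layer predictor, self-contained for prediction."""

    classifiers: dict  # kind -> ClassifierEnsemble
    encodings: tuple[str, ...]
    knn_reference: Optional[KnnReference]
    threshold: float
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)

    def predict_proba(
        self,
        records: LabeledDataset | Sequence[SequenceRecord],
        exclude_self: bool = False,
        explain: bool = False,
    ):
        """Final probability per record; with ``explain`` also the
        per-classifier layer-1 scores and per-encoding streams."""
        recs = records.records if isinstance(records, LabeledDataset) else list(records)
        mats = {}
        for enc in self.encodings:
            mats[enc] = encode_records(
                recs, enc, ref=self.knn_reference, exclude_self=exclude_self
            )
        per_clf_scores: dict[str, np.ndarray] = {}
        per_enc: dict[str, dict[str, np.ndarray]] = {}
        for kind, bundle in self.classifiers.items():
            streams = [
                predict_probability(bundle.models[enc], mats[enc])
                for enc in self.encodings
            ]
            per_enc[kind] = dict(zip(self.encodings, streams))
            per_clf_scores[kind] = layer1_combine(streams, bundle.weights)
        final = layer2_combine(list(per_clf_scores.values()))
        if explain:
            return final, {"classifier_scores": per_clf_scores, "encoding_scores": per_enc}
        return final

    def predict(
        self,
        records: LabeledDataset | Sequence[SequenceRecord],
        exclude_self: bool = False,
    ) -> np.ndarray:
        return classify(self.predict_proba(records, exclude_self=exclude_self), self.threshold)


def _fold_features(
    dataset: LabeledDataset,
    encoding: str,
    fold_indices,
    full_matrix: Optional[np.ndarray],
):
    """Materialise per-fold (X_train, y_train, X_val, y_val) matrices.

    For plain encodings this slices the precomputed full matrix.  For
    KNN the reference is rebuilt from the training folds only:
    training-fold rows are encoded against that reference with
    self-exclusion, validation rows against the same reference (their
    ids are absent from it by construction).
    """
    y = dataset.labels()
    out = []
    for tr, va in fold_indices:
        if encoding == "KNN":
            ref = build_knn_reference(dataset.subset(tr))
            tr_recs = [dataset.records[i] for i in tr]
            va_recs = [dataset.records[i] for i in va]
            Xtr = encode_knn_batch(tr_recs, ref, exclude_self=True)
            Xva = encode_knn_batch(va_recs, ref, exclude_self=False)
        else:
            assert full_matrix is not None
            Xtr = full_matrix[tr]
            Xva = full_matrix[va]
        out.append((Xtr, y[tr], Xva, y[va]))
    return out


def train_ensemble(dataset: LabeledDataset, config: PipelineConfig) -> TrainedEnsemble:
    """Run the full two-layer training protocol on a labeled dataset."""
    from .evaluate import stratified_kfold  # local import to avoid a cycle

    y = dataset.labels()
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError("training data must contain both classes")
    fold_indices = stratified_kfold(dataset, k=config.folds, seed=config.seed)

    # Full-data matrices; for KNN the full-data reference uses
    # self-exclusion so even the refit never sees a record's own label.
    full_ref = build_knn_reference(dataset) if "KNN" in config.encodings else None
    full_mats: dict[str, np.ndarray] = {}
    for enc in config.encodings:
        if enc == "KNN":
            full_mats[enc] = encode_knn_batch(
                dataset.records, full_ref, exclude_self=True
            )
        else:
            full_mats[enc] = encode_dataset(dataset, enc).values

    fold_feats = {
        enc: _fold_features(
            dataset, enc, fold_indices, None if enc == "KNN" else full_mats[enc]
        )
        for enc in config.encodings
    }

    classifiers: dict[str, ClassifierEnsemble] = {}
    for kind in config.classifiers:
        spec = config.spec_for(kind)
        models: dict[str, TrainedSingleModel] = {}
        sfs_results: dict[str, SfsResult] = {}
        oof_streams: list[np.ndarray] = []
        for enc in config.encodings:
            folds_enc = fold_feats[enc]
            params, tune_acc = grid_search(spec, folds_enc)
            logger.info("%s/%s: tuned params %s (CV acc %.4f)", kind, enc, params, tune_acc)

            selected = None
            if config.sfs and enc != "KNN":
                ranked = rank_features(full_mats[enc], y)
                sfs = sequential_forward_search(
                    full_mats[enc],
                    y,
                    ranked,
                    estimator_factory=lambda: build_estimator(
                        kind, params, seed=config.seed
                    ),
                    step=config.sfs_step,
                    fold_indices=fold_indices,
                )
                sfs_results[enc] = sfs
                selected = sfs.selected
                logger.info(
                    "%s/%s: SFS kept %d/%d features (CV acc %.4f)",
                    kind, enc, sfs.k, full_mats[enc].shape[1],
                    float(sfs.curve_accuracy.max()),
                )

            # Out-of-fold probabilities for the layer-1 weight search.
            oof = np.empty(len(dataset), dtype=float)
            for (tr, va), (Xtr, ytr, Xva, _) in zip(fold_indices, folds_enc):
                cols = selected if selected is not None else slice(None)
                fold_model = fit_model(
                    spec, params, Xtr[:, cols], ytr, encoding_name=""
                )
                oof[va] = predict_probability(fold_model, Xva[:, cols])
            oof_streams.append(oof)

            models[enc] = fit_model(
                spec,
                params,
                full_mats[enc],
                y,
                encoding_name=enc,
                selected_features=selected,
                cv_accuracy=tune_acc,
            )
        weights = optimize_layer1_weights(
            oof_streams,
            y,
            grid_step=config.grid_step,
            threshold=config.threshold,
            encodings=config.encodings,
        )
        logger.info("%s: layer-1 weights %s", kind, weights.weights)
        classifiers[kind] = ClassifierEnsemble(
            kind=kind, models=models, weights=weights, sfs_results=sfs_results
        )

    provenance = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "package_version": _pkg_version,
        "n_pos": dataset.n_pos,
        "n_neg": dataset.n_neg,
        "seed": config.seed,
        "trained_at": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    return TrainedEnsemble(
        classifiers=classifiers,
        encodings=config.encodings,
        knn_reference=full_ref,
        threshold=config.threshold,
        config=config,
        provenance=provenance,
    )


def save_ensemble(ensemble: TrainedEnsemble, path) -> None:
    """Persist a trained ensemble as a single archive file."""
    joblib.dump({"schema_version": ARCHIVE_SCHEMA_VERSION, "ensemble": ensemble}, path)


def load_ensemble(path) -> TrainedEnsemble:
    payload = joblib.load(path)
    if payload.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported archive schema {payload.get('schema_version')!r}"
        )
    return payload["ensemble"]
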