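"""RBF-SVM classification harness shared by the EEG and music pipelines.

Grid search over (C, gamma) with stratified 10-fold cross-validation,
min-max feature scaling fitted on training folds only, confusion
matrices, and accuracy-based channel ranking / top-k channel
selection for EEG portability studies.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from emomap.types import (
    ChannelRanking,
    CVResult,
    EEGRecording,
    FeatureTable,
    InvalidInputError,
    SVMConfig,
)


class MinMaxScaler:
    """Per-feature affine map to [-1, 1] learned from training data.

    Constant features map to 0 everywhere.
    """

    def __init__(self) -> None:
        self.mins: np.ndarray | None = None
        self.maxs: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None or self.maxs is None:
            raise InvalidInputError("scaler has not been fitted")
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(span > 0, -1.0 + 2.0 * (X - self.mins) / span, 0.0)
        return scaled


def scale_features(
    train: FeatureTable, apply_to: FeatureTable | None = None
) -> tuple[FeatureTable, FeatureTable | None, MinMaxScaler]:
    """Fit min-max scaling on ``train`` and apply it to both tables."""
    scaler = MinMaxScaler().fit(train.X)
    scaled_train = FeatureTable(
        ids=train.ids,
        X=scaler.transform(train.X),
        feature_names=train.feature_names,
        labels=train.labels,
    )
    scaled_other = None
    if apply_to is not None:
        if apply_to.feature_names != train.feature_names:
            raise InvalidInputError("feature-name mismatch between tables")
        scaled_other = FeatureTable(
            ids=apply_to.ids,
            X=scaler.transform(apply_to.X),
            feature_names=apply_to.feature_names,
            labels=apply_to.labels,
        )
    return scaled_train, scaled_other, scaler


def confusion_matrix(
    true_labels: list[str], predicted_labels: list[str], class_names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Count matrix: entry (i, j) = class-i instances predicted as class j."""
    if len(true_labels) != len(predicted_labels):
        raise InvalidInputError("label lists must have equal length")
    if class_names is None:
        class_names = sorted(set(true_labels) | set(predicted_labels))
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return counts, class_names


def _cv_folds(labels: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


def grid_search_cv(table: FeatureTable, config: SVMConfig | None = None) -> CVResult:
    """Stratified k-fold CV accuracy over the (C, gamma) grid.

    For each grid point the table is re-split with the seeded fold
    assignment, features are min-max scaled on the training folds
    only, and an RBF SVM is fitted per fold. Returns the best grid
    point's per-fold accuracies, their mean and max, and the pooled
    confusion matrix across its test folds.
    """
    config = config or SVMConfig()
    labels = np.asarray(table.labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < config.folds]
    if small.size:
        raise InvalidInputError(
            f"classes with fewer than {config.folds} instances: {small.tolist()}"
        )
    folds = _cv_folds(labels, config.folds, config.seed)
    class_names = classes.tolist()

    best: tuple[float, float, float] | None = None  # (mean_acc, C, gamma)
    best_fold_accs: np.ndarray | None = None
    best_preds: np.ndarray | None = None
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            fold_accs = np.empty(len(folds))
            preds = np.empty(labels.size, dtype=labels.dtype)
            for fi, (tr, te) in enumerate(folds):
                scaler = MinMaxScaler().fit(table.X[tr])
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(scaler.transform(table.X[tr]), labels[tr])
                p = clf.predict(scaler.transform(table.X[te]))
                preds[te] = p
                fold_accs[fi] = float(np.mean(p == labels[te]))
            mean_acc = float(fold_accs.mean())
            if best is None or mean_acc > best[0]:
                best = (mean_acc, C, gamma)
                best_fold_accs = fold_accs
                best_preds = preds
    assert best is not None and best_fold_accs is not None and best_preds is not None
    confusion, _ = confusion_matrix(labels.tolist(), best_preds.tolist(), class_names)
    return CVResult(
        fold_accuracies=best_fold_accs,
        mean_accuracy=best[0],
        max_accuracy=float(best_fold_accs.max()),
        best_C=best[1],
        best_gamma=best[2],
        confusion=confusion,
        class_names=class_names,
    )


def rank_channels(acc_channel: dict[str, float] | list[tuple[str, float]]) -> ChannelRanking:
    """Order channels by descending accuracy, ties by original index."""
    items = list(acc_channel.items()) if isinstance(acc_channel, dict) else list(acc_channel)
    if not items:
        raise InvalidInputError("no channel accuracies given")
    order = sorted(range(len(items)), key=lambda i: (-items[i][1], i))
    return ChannelRanking(
        channels=[items[i][0] for i in order],
        accuracies=[float(items[i][1]) for i in order],
    )


def feature_table_from_recordings(
    recordings: list[EEGRecording],
    labels: list[str],
    channels: list[str] | None = None,
    **extract_kwargs,
) -> FeatureTable:
    """Build a feature table by running the EEG pipeline per trial.

    ``channels`` restricts extraction to a subset (used for top-k
    channel evaluation).
    """
    from emomap import eeg_features

    if len(recordings) != len(labels):
        raise InvalidInputError("recordings and labels must align")
    rows, ids = [], []
    feature_names: list[str] | None = None
    for rec in recordings:
        if channels is not None:
            missing = [c for c in channels if c not in rec.channel_names]
            if missing:
                raise InvalidInputError(f"channels not in recording: {missing}")
            idx = [rec.channel_names.index(c) for c in channels]
            rec = EEGRecording(
                channel_names=[rec.channel_names[i] for i in idx],
                samples=rec.samples[idx],
                fs=rec.fs,
                trial_id=rec.trial_id,
                subject_id=rec.subject_id,
            )
        fv = eeg_features.extract_eeg_features(rec, **extract_kwargs)
        rows.append(fv.values)
        ids.append(rec.trial_id)
        if feature_names is None:
            feature_names = fv.feature_names()
    assert feature_names is not None
    return FeatureTable(ids=ids, X=np.vstack(rows), feature_names=feature_names, labels=list(labels))


def evaluate_topk_channels(
    recordings: list[EEGRecording],
    labels: list[str],
    ranking: ChannelRanking,
    ks: list[int],
    config: SVMConfig | None = None,
    **extract_kwargs,
) -> dict[int, CVResult]:
    """Re-run grid-search CV restricted to the top-k ranked channels."""
    n_channels = len(ranking.channels)
    bad = [k for k in ks if not 1 <= k <= n_channels]
    if bad:
        raise InvalidInputError(f"k out of range [1, {n_channels}]: {bad}")
    results: dict[int, CVResult] = {}
    for k in ks:
        table = feature_table_from_recordings(
            recordings, labels, channels=ranking.channels[:k], **extract_kwargs
        )
        results[k] = grid_search_cv(table, config)
    return results
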