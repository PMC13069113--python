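"""Linear-SVM decoding with recording-wise temporal cross-validation.

The decoder is a 3-class linear SVM (one-vs-rest, C = 1) on z-scored
PSD features; standardization parameters are fitted on training rows
only.  Cross-validation respects recording chronology: the ten offline
recordings form five consecutive pairs, each pair serving once as the
held-out test set while the remaining eight recordings train the model.
The fold with the highest accuracy supplies the model used for the
online session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .features import FeatureMatrix

SVM_C = 1.0
N_RECORDINGS = 10
FOLD_TEST_SIZE = 2


@dataclass
class TrainedModel:
    """Standardizer + linear decision functions, frozen after fitting."""

    mean: np.ndarray           # per-feature training mean
    scale: np.ndarray          # per-feature training scale
    coef: np.ndarray           # (n_classes, n_features) or (1, n) binary
    intercept: np.ndarray
    classes: list[str]         # sklearn's fitted class order
    class_order: list[str]     # reporting order for confusion matrices
    training_recording_ids: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature count {X.shape[1]} does not match the model's "
                f"{self.n_features}"
            )
        Z = (X - self.mean) / self.scale
        return Z @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        if len(self.classes) == 2:
            idx = (scores.ravel() > 0).astype(int)
        else:
            idx = np.argmax(scores, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def _resolve_class_order(labels: list[str], class_order) -> list[str]:
    present = list(dict.fromkeys(labels))
    if class_order is None:
        return sorted(present)
    missing = set(present) - set(class_order)
    if missing:
        raise ValueError(f"labels {sorted(missing)} missing from class order")
    return list(class_order)


def train_model(features: FeatureMatrix, rows: np.ndarray | None = None,
                class_order: list[str] | None = None) -> TrainedModel:
    """Fit the standardized linear SVM on a subset of trials.

    ``rows`` selects the training trials (all by default).  Scaling
    parameters come from the training rows alone so held-out data never
    leaks into the fit.
    """
    if rows is None:
        rows = np.arange(features.X.shape[0])
    rows = np.asarray(rows)
    X = features.X[rows]
    y = np.asarray(features.labels, dtype=object)[rows]
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")

    scaler = StandardScaler().fit(X)
    svm = LinearSVC(C=SVM_C, random_state=0, max_iter=20000)
    svm.fit(scaler.transform(X), y)
    return TrainedModel(
        mean=scaler.mean_, scale=scaler.scale_,
        coef=np.atleast_2d(svm.coef_), intercept=np.atleast_1d(svm.intercept_),
        classes=list(svm.classes_),
        class_order=_resolve_class_order(list(y), class_order),
        training_recording_ids=sorted(set(np.asarray(features.recording_ids,
                                                     dtype=object)[rows])),
    )


def evaluate(model: TrainedModel, features: FeatureMatrix
             ) -> tuple[float, pd.DataFrame]:
    """Accuracy (%) and confusion matrix (rows = true class) on a set."""
    pred = model.predict(features.X)
    true = np.asarray(features.labels, dtype=object)
    order = model.class_order
    confusion = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for t, p in zip(true, pred):
        confusion.loc[t, p] += 1
    accuracy = 100.0 * float(np.mean(pred == true))
    return accuracy, confusion


@dataclass
class CVResult:
    """Per-fold accuracies and confusion matrices of the temporal CV."""

    fold_test_ids: list[list[str]]
    fold_accuracies: list[float]        # %
    fold_confusions: list[pd.DataFrame]
    mean_accuracy: float                # %
    std_accuracy: float                 # %, population SD across folds
    best_fold: int                      # earliest argmax of fold accuracy
    models: list[TrainedModel] = field(default_factory=list, repr=False)


def concat_features(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Row-wise concatenation of feature matrices with identical columns."""
    first = blocks[0]
    for b in blocks[1:]:
        if b.channels != first.channels or not np.array_equal(b.freqs, first.freqs):
            raise ValueError("feature blocks have mismatched columns")
    return FeatureMatrix(
        X=np.vstack([b.X for b in blocks]),
        labels=[l for b in blocks for l in b.labels],
        recording_ids=[r for b in blocks for r in b.recording_ids],
        freqs=first.freqs, channels=first.channels,
    )


def temporal_cv(recordings: list[FeatureMatrix],
                class_order: list[str] | None = None) -> CVResult:
    """Five-fold cross-validation over ten chronologically ordered recordings.

    Fold i tests on the consecutive pair (2i, 2i+1) and trains on the
    other eight recordings, so every recording is tested exactly once.
    """
    if len(recordings) != N_RECORDINGS:
        raise ValueError(
            f"temporal CV needs exactly {N_RECORDINGS} recordings, "
            f"got {len(recordings)}"
        )
    accuracies, confusions, test_ids, models = [], [], [], []
    for i in range(N_RECORDINGS // FOLD_TEST_SIZE):
        test = recordings[2 * i: 2 * i + FOLD_TEST_SIZE]
        train = [r for j, r in enumerate(recordings)
                 if not 2 * i <= j < 2 * i + FOLD_TEST_SIZE]
        model = train_model(concat_features(train), class_order=class_order)
        acc, conf = evaluate(model, concat_features(test))
        accuracies.append(acc)
        confusions.append(conf)
        test_ids.append([t.recording_ids[0] for t in test])
        models.append(model)
    accuracies_arr = np.asarray(accuracies)
    return CVResult(
        fold_test_ids=test_ids, fold_accuracies=accuracies,
        fold_confusions=confusions,
        mean_accuracy=float(accuracies_arr.mean()),
        std_accuracy=float(accuracies_arr.std()),
        best_fold=int(np.argmax(accuracies_arr)),
        models=models,
    )


def select_online_model(cv: CVResult,
                        models: list[TrainedModel] | None = None) -> TrainedModel:
    """Model of the best cross-validation fold (earliest on ties)."""
    models = cv.models if models is None else models
    if not models:
        raise ValueError("no per-fold models available")
    return models[cv.best_fold]
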