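"""Linear-SVM training, temporal cross-validation, online-model selection."""

import numpy as np
import pytest

from vibci.classify import (
    CVResult,
    concat_features,
    evaluate,
    select_online_model,
    temporal_cv,
    train_model,
)
from vibci.features import FeatureMatrix
from vibci.preprocess import extract_epochs, filter_chain
from vibci.recording import REST_LABEL, imagery_label
from vibci.simulate import ProtocolSpec, make_subject_profile, simulate_recording

from conftest import FS

CLASS_ORDER = [imagery_label(5.0), REST_LABEL, imagery_label(9.0)]


def _gaussian_features(seed=0, n_per_class=20, separation=10.0, n_feat=6,
                       recording_id="r0"):
    """Three Gaussian clusters, one per class, optionally well separated."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for i, label in enumerate(CLASS_ORDER):
        center = np.zeros(n_feat)
        center[i] = separation
        X.append(center + rng.standard_normal((n_per_class, n_feat)))
        labels += [label] * n_per_class
    freqs = np.arange(3.0, 3.0 + n_feat / 2, 0.5)[: n_feat // 2]
    return FeatureMatrix(np.vstack(X), labels,
                         [recording_id] * (3 * n_per_class),
                         freqs=freqs, channels=("Oz", "O1"))


def _simulated_blocks(profile, n=10, seed0=0):
    step3 = ProtocolSpec.step_3((5.0, 9.0))
    blocks = []
    for i in range(n):
        rec = simulate_recording(step3, profile, couple=(5.0, 9.0),
                                 seed=seed0 + i, fs=FS,
                                 recording_id=f"rec{i:02d}")
        blocks.append(build_features_from(rec, step3))
    return blocks


def build_features_from(rec, protocol):
    from vibci.features import build_features
    return build_features(extract_epochs(filter_chain(rec), protocol))


class TestTrainModel:
    def test_separable_clusters_reach_full_training_accuracy(self):
        fm = _gaussian_features(separation=10.0)
        model = train_model(fm, class_order=CLASS_ORDER)
        acc, confusion = evaluate(model, fm)
        assert acc == 100.0
        assert np.array_equal(np.diag(confusion), [20, 20, 20])

    def test_duplicated_training_set_gives_identical_decisions(self):
        fm = _gaussian_features(separation=2.0)
        doubled = concat_features([fm, fm])
        a = train_model(fm, class_order=CLASS_ORDER)
        b = train_model(doubled, class_order=CLASS_ORDER)
        probe = _gaussian_features(seed=99, separation=2.0)
        assert np.array_equal(a.predict(probe.X), b.predict(probe.X))

    def test_single_class_training_rejected(self):
        fm = _gaussian_features()
        rows = np.arange(20)  # first class only
        with pytest.raises(ValueError, match="single class"):
            train_model(fm, rows=rows)

    def test_scaling_parameters_come_from_training_rows_only(self):
        """Dropping held-out rows never changes the fitted model."""
        fm = _gaussian_features(n_per_class=30)
        train_rows = np.arange(0, 90, 2)
        full = train_model(fm, rows=train_rows, class_order=CLASS_ORDER)
        reduced_matrix = FeatureMatrix(
            fm.X[train_rows],
            [fm.labels[i] for i in train_rows],
            [fm.recording_ids[i] for i in train_rows],
            freqs=fm.freqs, channels=fm.channels)
        reduced = train_model(reduced_matrix, class_order=CLASS_ORDER)
        assert np.array_equal(full.mean, reduced.mean)
        assert np.array_equal(full.scale, reduced.scale)
        assert np.array_equal(full.coef, reduced.coef)


class TestEvaluate:
    def test_perfect_predictions_on_balanced_trials(self):
        fm = _gaussian_features(separation=10.0)
        model = train_model(fm, class_order=CLASS_ORDER)
        acc, confusion = evaluate(model, fm)
        assert acc == 100.0
        assert confusion.to_numpy().sum() == 60

    def test_constant_predictor_scores_the_base_rate(self):
        fm = _gaussian_features(separation=10.0)
        model = train_model(fm, class_order=CLASS_ORDER)
        # force a constant decision by biasing one intercept hugely
        model.intercept = model.intercept + np.array([1e6, 0.0, 0.0])
        acc, confusion = evaluate(model, fm)
        assert acc == pytest.approx(100.0 / 3.0)
        assert confusion[model.classes[0]].sum() == 60

    def test_feature_count_mismatch_rejected(self):
        model = train_model(_gaussian_features(), class_order=CLASS_ORDER)
        with pytest.raises(ValueError, match="feature count"):
            model.predict(np.zeros((4, 99)))


class TestTemporalCV:
    def test_each_recording_tested_exactly_once(self):
        blocks = [_gaussian_features(seed=i, recording_id=f"rec{i}")
                  for i in range(10)]
        cv = temporal_cv(blocks, class_order=CLASS_ORDER)
        tested = [rid for fold in cv.fold_test_ids for rid in fold]
        assert sorted(tested) == sorted(f"rec{i}" for i in range(10))
        assert all(len(fold) == 2 for fold in cv.fold_test_ids)

    def test_folds_train_on_eight_recordings(self):
        blocks = [_gaussian_features(seed=i, recording_id=f"rec{i}")
                  for i in range(10)]
        cv = temporal_cv(blocks, class_order=CLASS_ORDER)
        assert len(cv.models) == 5
        assert all(len(m.training_recording_ids) == 8 for m in cv.models)

    def test_wrong_recording_count_rejected(self):
        blocks = [_gaussian_features(seed=i) for i in range(7)]
        with pytest.raises(ValueError, match="exactly 10"):
            temporal_cv(blocks)

    def test_confusion_rows_sum_to_fold_class_counts(self):
        blocks = [_gaussian_features(seed=i, recording_id=f"rec{i}")
                  for i in range(10)]
        cv = temporal_cv(blocks, class_order=CLASS_ORDER)
        for conf in cv.fold_confusions:
            assert conf.sum(axis=1).tolist() == [40, 40, 40]

    def test_accuracy_is_monotone_in_response_gain(self):
        """Mean CV accuracy does not decrease across three gain levels."""
        means = []
        for gain in (0.0, 2.5, 5.0):
            accs = []
            for seed in range(5):
                profile = make_subject_profile(
                    seed, {"gains": {5: gain, 9: gain}})
                cv = temporal_cv(_simulated_blocks(profile, seed0=100 * seed),
                                 class_order=CLASS_ORDER)
                accs.append(cv.mean_accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] <= means[2]


class TestSelectOnlineModel:
    def _cv_with_accuracies(self, accs):
        models = [object() for _ in accs]
        arr = np.asarray(accs, dtype=float)
        return CVResult(fold_test_ids=[[] for _ in accs],
                        fold_accuracies=list(accs),
                        fold_confusions=[],
                        mean_accuracy=float(arr.mean()),
                        std_accuracy=float(arr.std()),
                        best_fold=int(np.argmax(arr)),
                        models=models)

    def test_earliest_of_tied_maxima_wins(self):
        cv = self._cv_with_accuracies([60, 70, 65, 70, 50])
        assert select_online_model(cv) is cv.models[1]

    def test_all_equal_selects_first_fold(self):
        cv = self._cv_with_accuracies([55, 55, 55, 55, 55])
        assert select_online_model(cv) is cv.models[0]

    def test_selection_is_stable_across_calls(self):
        cv = self._cv_with_accuracies([40, 80, 60, 20, 10])
        assert select_online_model(cv) is select_online_model(cv)
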