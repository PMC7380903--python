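import numpy as np
import pytest

from rehabhar import (
    ChannelNormalizer,
    CNNConfig,
    ExerciseClass,
    SensorSubset,
    build_window_tensor,
    fit_normalizer,
    load_recognizer,
    predict,
    predict_windows,
    save_recognizer,
    train_recognizer,
    windows_to_tensor,
)
from rehabhar.recognizer import WindowCNNClassifier

from conftest import make_toy_windows


class TestWindowTensor:
    def test_subset_shapes(self, tiny_windows):
        w = tiny_windows[0]
        assert build_window_tensor(w, SensorSubset.ACCEL).shape == (30, 3)
        assert build_window_tensor(w, SensorSubset.GYRO).shape == (30, 3)
        assert build_window_tensor(w, SensorSubset.ACCEL_GYRO).shape == (30, 6)

    def test_gyro_is_last_three_columns_of_combined(self, tiny_windows):
        w = tiny_windows[0]
        both = build_window_tensor(w, SensorSubset.ACCEL_GYRO)
        np.testing.assert_array_equal(
            build_window_tensor(w, SensorSubset.GYRO), both[:, 3:]
        )
        np.testing.assert_array_equal(
            build_window_tensor(w, SensorSubset.ACCEL), both[:, :3]
        )

    def test_first_row_is_first_sample(self, tiny_windows):
        w = tiny_windows[0]
        np.testing.assert_array_equal(
            build_window_tensor(w, SensorSubset.ACCEL_GYRO)[0], w.values[0]
        )


class TestNormalizer:
    def test_training_set_becomes_standard(self, tiny_windows):
        norm = fit_normalizer(tiny_windows, SensorSubset.ACCEL_GYRO)
        X, _ = windows_to_tensor(tiny_windows, SensorSubset.ACCEL_GYRO)
        Z = norm.transform(X)
        np.testing.assert_allclose(Z.mean(axis=(0, 1)), 0.0, atol=1e-6)
        np.testing.assert_allclose(Z.std(axis=(0, 1)), 1.0, atol=1e-6)

    def test_constant_channel_maps_to_zero(self):
        X = np.ones((4, 30, 3)) * 7.0
        Z = ChannelNormalizer().fit(X).transform(X)
        np.testing.assert_array_equal(Z, 0.0)

    def test_train_stats_shift_test_mean_predictably(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 30, 3))
        norm = ChannelNormalizer().fit(X)
        delta = np.array([1.0, -2.0, 0.5])
        Z = norm.transform(X + delta)
        expected = norm.transform(X).mean(axis=(0, 1)) + delta / norm.scale_
        np.testing.assert_allclose(Z.mean(axis=(0, 1)), expected, atol=1e-9)


class TestTraining:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        windows = make_toy_windows(seed=1)
        model = train_recognizer(
            windows, SensorSubset.ACCEL_GYRO, CNNConfig(epochs=50, seed=0)
        )
        X, y = windows_to_tensor(windows, SensorSubset.ACCEL_GYRO)
        assert model.estimator.score(X, y) == 1.0

    def test_heldout_toy_windows_classified_correctly(self):
        train_w = make_toy_windows(seed=1)
        test_w = make_toy_windows(seed=99)
        model = train_recognizer(
            train_w, SensorSubset.ACCEL_GYRO, CNNConfig(epochs=50, seed=0)
        )
        assert predict_windows(model, test_w) == [w.label for w in test_w]

    def test_seeded_training_is_deterministic(self):
        windows = make_toy_windows(seed=2)
        X, _ = windows_to_tensor(windows, SensorSubset.ACCEL_GYRO)
        cfg = CNNConfig(epochs=10, seed=7)
        m1 = train_recognizer(windows, SensorSubset.ACCEL_GYRO, cfg)
        m2 = train_recognizer(windows, SensorSubset.ACCEL_GYRO, cfg)
        np.testing.assert_array_equal(
            m1.estimator.predict_proba(X), m2.estimator.predict_proba(X)
        )

    def test_metadata_records_subset_and_classes(self, tiny_windows, fast_cnn_config):
        model = train_recognizer(tiny_windows, SensorSubset.GYRO, fast_cnn_config)
        assert model.subset is SensorSubset.GYRO
        assert model.classes == sorted(
            {w.label for w in tiny_windows}, key=int
        )
        assert model.fingerprint

    def test_single_class_training_rejected(self):
        windows = [w for w in make_toy_windows(seed=0)
                   if w.label is ExerciseClass.NO_EXERCISE]
        with pytest.raises(ValueError, match="2 classes"):
            train_recognizer(windows, SensorSubset.ACCEL, CNNConfig(epochs=1))

    def test_architecture_matches_description(self, tiny_windows, fast_cnn_config):
        # 8 and 16 feature maps, 32 dense nodes, one output per class
        model = train_recognizer(tiny_windows, SensorSubset.ACCEL_GYRO, fast_cnn_config)
        p = model.estimator.net_.params
        assert p["w1"].shape == (5, 6, 8)
        assert p["w2"].shape == (5, 8, 16)
        assert p["w3"].shape[1] == 32
        assert p["w4"].shape == (32, 5)


class TestPrediction:
    def test_probabilities_sum_to_one(self, tiny_windows, fast_cnn_config):
        model = train_recognizer(tiny_windows, SensorSubset.ACCEL_GYRO, fast_cnn_config)
        rng = np.random.default_rng(0)
        for w in rng.choice(len(tiny_windows), size=10, replace=False):
            probs, cls = predict(model, tiny_windows[int(w)])
            assert probs.shape == (5,)
            assert np.all(probs >= 0)
            assert abs(probs.sum() - 1.0) < 1e-6
            assert cls is ExerciseClass(int(np.argmax(probs)))

    def test_prediction_ignores_window_metadata(self, tiny_windows, fast_cnn_config):
        import dataclasses

        model = train_recognizer(tiny_windows, SensorSubset.ACCEL_GYRO, fast_cnn_config)
        w = tiny_windows[3]
        shifted = dataclasses.replace(w, start=w.start + 999, segment=77)
        p1, c1 = predict(model, w)
        p2, c2 = predict(model, shifted)
        np.testing.assert_array_equal(p1, p2)
        assert c1 is c2

    def test_subset_mismatch_rejected(self, tiny_windows, fast_cnn_config):
        model = train_recognizer(tiny_windows, SensorSubset.ACCEL, fast_cnn_config)
        X, _ = windows_to_tensor(tiny_windows, SensorSubset.ACCEL_GYRO)
        with pytest.raises(ValueError, match="mismatch"):
            model.estimator.predict(X)

    def test_accuracy_invariant_under_consistent_channel_permutation(self):
        import dataclasses

        windows = make_toy_windows(seed=3, n_per_class=20)
        perm = [2, 0, 1, 5, 3, 4]
        permuted = [dataclasses.replace(w, values=w.values[:, perm]) for w in windows]
        cfg = CNNConfig(epochs=30, seed=0)
        acc = []
        for ws in (windows, permuted):
            model = train_recognizer(ws, SensorSubset.ACCEL_GYRO, cfg)
            X, y = windows_to_tensor(ws, SensorSubset.ACCEL_GYRO)
            acc.append(model.estimator.score(X, y))
        assert acc[0] == acc[1]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_windows, fast_cnn_config):
        model = train_recognizer(tiny_windows, SensorSubset.ACCEL_GYRO, fast_cnn_config)
        save_recognizer(model, tmp_path / "model")
        loaded = load_recognizer(tmp_path / "model")
        X, _ = windows_to_tensor(tiny_windows, SensorSubset.ACCEL_GYRO)
        np.testing.assert_array_equal(
            model.estimator.predict_proba(X), loaded.estimator.predict_proba(X)
        )
        assert loaded.subset is model.subset
        assert loaded.classes == model.classes


class TestSklearnProtocol:
    def test_get_set_params_round_trip(self):
        est = WindowCNNClassifier(epochs=3, random_state=1)
        params = est.get_params()
        assert params["epochs"] == 3
        clone = WindowCNNClassifier().set_params(**params)
        assert clone.get_params() == params
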