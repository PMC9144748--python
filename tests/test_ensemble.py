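"""Two-stage ensemble: splitting, training, routing, prediction, counting."""

import numpy as np
import pytest

import gaitcount as gc
from gaitcount.ensemble import ENSEMBLE_COMPONENTS, make_estimator

# shrunken learner settings for fast unit-level fits (study-scale settings
# are exercised by the acceptance suite)
FAST_HP = {
    "random_forest": {"n_estimators": 30},
    "svm": {},
    "mlp": {"hidden_layer_sizes": (32, 16), "max_iter": 120},
    "knn": {},
    "hist_gradient_boost": {"max_iter": 40},
    "cnn": {"epochs": 10},
}


class TestModelSpec:
    def test_valid_roles(self):
        gc.ModelSpec("random_forest", "classifier")
        gc.ModelSpec("ensemble", "regressor")

    @pytest.mark.parametrize(
        "alg, role",
        [("ensemble", "classifier"), ("nonsense", "regressor"), ("svm", "oracle")],
    )
    def test_invalid_specs_rejected(self, alg, role):
        with pytest.raises(ValueError):
            gc.ModelSpec(alg, role)

    def test_ensemble_has_no_single_estimator(self):
        with pytest.raises(ValueError):
            make_estimator(gc.ModelSpec("ensemble", "regressor"))


class TestSplitDataset:
    def test_random_mode_exact_ratio_and_determinism(self, small_dataset):
        tr, te = gc.split_dataset(small_dataset, 0.7, mode="random", seed=5)
        assert len(tr) == round(0.7 * len(small_dataset))
        assert len(tr) + len(te) == len(small_dataset)
        tr2, te2 = gc.split_dataset(small_dataset, 0.7, mode="random", seed=5)
        np.testing.assert_array_equal(tr.window_starts, tr2.window_starts)
        np.testing.assert_array_equal(te.window_starts, te2.window_starts)

    def test_chronological_mode_has_no_sample_overlap(self, small_dataset):
        tr, te = gc.split_dataset(small_dataset, 0.7, mode="chronological")
        window_ms = 2000
        for rec in np.unique(small_dataset.recording_ids):
            tr_starts = tr.window_starts[tr.recording_ids == rec]
            te_starts = te.window_starts[te.recording_ids == rec]
            if len(tr_starts) and len(te_starts):
                assert tr_starts.max() + window_ms <= te_starts.min()

    def test_chronological_ratio_approximate(self, small_dataset):
        tr, te = gc.split_dataset(small_dataset, 0.7, mode="chronological")
        frac = len(tr) / (len(tr) + len(te))
        assert 0.65 < frac < 0.72

    def test_bad_fraction_rejected(self, small_dataset):
        for frac in (0.0, 1.0, -0.3, 1.7):
            with pytest.raises(ValueError):
                gc.split_dataset(small_dataset, frac)


def _tiny_dataset(n_per_pos=40, seed=0):
    rng = np.random.default_rng(seed)
    feats, labels, positions = [], [], []
    for i, pos in enumerate(gc.POSITIONS):
        feats.append(rng.normal(9.81, 0.5 + i, size=(n_per_pos, 60)))
        labels.append(rng.integers(2, 6, size=n_per_pos))
        positions += [pos] * n_per_pos
    return (np.vstack(feats), np.concatenate(labels), np.asarray(positions, dtype=object))


class TestTraining:
    def test_full_seven_algorithm_bank_shape(self):
        X, y, pos = _tiny_dataset()
        model = gc.EnsembleStepCounter(
            regressor_algorithms=tuple(a for a in gc.ALGORITHMS),
            regressor_hyperparams=FAST_HP,
            classifier_hyperparams={"n_estimators": 20},
            random_state=0,
        ).fit(X, y, positions=pos)
        assert set(model.regressors_) == set(gc.POSITIONS)
        for bank in model.regressors_.values():
            # ensemble is derived from components, so 6 fitted estimators per position
            assert set(bank) == set(gc.ALGORITHMS) - {"ensemble"}

    def test_single_regressor_bank(self):
        X, y, pos = _tiny_dataset()
        model = gc.EnsembleStepCounter(
            regressor_algorithms=("random_forest",),
            regressor_hyperparams=FAST_HP,
            classifier_hyperparams={"n_estimators": 20},
        ).fit(X, y, positions=pos)
        for bank in model.regressors_.values():
            assert list(bank) == ["random_forest"]

    def test_single_position_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 60))
        y = rng.integers(0, 5, 30)
        with pytest.raises(gc.TrainingDataError):
            gc.EnsembleStepCounter().fit(X, y, positions=["pocket"] * 30)

    def test_positions_required(self):
        X, y, _ = _tiny_dataset()
        with pytest.raises(ValueError):
            gc.EnsembleStepCounter().fit(X, y)

    def test_seeded_training_reproducible(self, small_split):
        train, test = small_split
        kwargs = dict(
            regressor_algorithms=("random_forest",),
            regressor_hyperparams=FAST_HP,
            classifier_hyperparams={"n_estimators": 20},
            random_state=3,
        )
        a = gc.EnsembleStepCounter(**kwargs).fit_dataset(train)
        b = gc.EnsembleStepCounter(**kwargs).fit_dataset(train)
        np.testing.assert_array_equal(
            a.predict(test.features, positions=test.positions, algorithm="random_forest"),
            b.predict(test.features, positions=test.positions, algorithm="random_forest"),
        )


class TestPrediction:
    def test_classifier_overfits_training_windows(self, small_model, small_split):
        train, _ = small_split
        predicted = small_model.classify_position(train.features[:200])
        assert (predicted == train.positions[:200]).mean() > 0.97

    def test_constant_window_gets_some_valid_label(self, small_model):
        flat = np.full((1, 60), 9.81)
        assert small_model.classify_position(flat)[0] in gc.POSITIONS

    def test_batch_order_preserved(self, small_model, small_split):
        _, test = small_split
        batch = small_model.classify_position(test.features[:50])
        singles = [small_model.classify_position(test.features[i : i + 1])[0] for i in range(50)]
        assert list(batch) == singles

    def test_feature_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.classify_position(np.zeros((1, 59)))
        with pytest.raises(ValueError):
            small_model.predict_window_steps(np.zeros(10), "pocket")

    def test_unknown_position_or_algorithm_rejected(self, small_model, small_split):
        _, test = small_split
        row = test.features[0]
        with pytest.raises(KeyError):
            small_model.predict_window_steps(row, "pocket", algorithm="cnn")  # not trained
        with pytest.raises(KeyError):
            small_model.predict(test.features[:1], positions=["nowhere"])

    def test_predictions_non_negative(self, small_model, small_split):
        _, test = small_split
        for alg in ("random_forest", "svm", "mlp", "ensemble"):
            assert np.all(small_model.predict(test.features, positions=test.positions,
                                              algorithm=alg) >= 0)

    def test_routing_sends_windows_to_own_position_bank(self, small_model, small_split):
        """With oracle positions injected, each window's prediction equals the
        prediction of that position's own regressor."""
        _, test = small_split
        preds = small_model.predict(test.features[:90], positions=test.positions[:90],
                                    algorithm="random_forest")
        for pos in gc.POSITIONS:
            m = test.positions[:90] == pos
            if m.any():
                direct = small_model.regressors_[pos]["random_forest"].predict(test.features[:90][m])
                np.testing.assert_allclose(preds[m], np.maximum(direct, 0.0))

    def test_ensemble_is_convex_combination_of_components(self, small_model, small_split):
        _, test = small_split
        X, pos = test.features[:120], test.positions[:120]
        comp = np.stack([
            np.maximum(small_model.predict(X, positions=pos, algorithm=a), 0.0)
            for a in ENSEMBLE_COMPONENTS
        ])
        ens = small_model.predict(X, positions=pos, algorithm="ensemble")
        assert np.all(ens >= comp.min(axis=0) - 1e-9)
        assert np.all(ens <= comp.max(axis=0) + 1e-9)

    def test_degenerate_weights_reduce_to_single_component(self, small_split):
        train, test = small_split
        model = gc.EnsembleStepCounter(
            ensemble_weights={"svm": 1.0, "mlp": 0.0, "random_forest": 0.0},
            regressor_hyperparams=FAST_HP,
            classifier_hyperparams={"n_estimators": 20},
        ).fit_dataset(train)
        svm = model.predict(test.features[:40], positions=test.positions[:40], algorithm="svm")
        ens = model.predict(test.features[:40], positions=test.positions[:40], algorithm="ensemble")
        np.testing.assert_allclose(ens, svm)

    def test_uniform_weighted_mean(self, small_model, monkeypatch):
        """Component predictions (2, 3, 4) with uniform weights average to 3."""
        bank = small_model.regressors_["pocket"]

        class Stub:
            def __init__(self, value):
                self.value = value

            def predict(self, X):
                return np.full(len(X), self.value)

        monkeypatch.setitem(bank, "svm", Stub(2.0))
        monkeypatch.setitem(bank, "mlp", Stub(3.0))
        monkeypatch.setitem(bank, "random_forest", Stub(4.0))
        out = small_model.predict_window_steps(np.zeros(60) + 9.81, "pocket", "ensemble")
        assert out == pytest.approx(3.0)

    def test_invalid_weights_rejected(self, small_dataset):
        for weights in (
            {"svm": 0.5, "mlp": 0.5},  # missing component
            {"svm": 0.7, "mlp": 0.6, "random_forest": -0.3},  # negative
            {"svm": 0.5, "mlp": 0.4, "random_forest": 0.3},  # sum != 1
        ):
            with pytest.raises(ValueError):
                gc.EnsembleStepCounter(ensemble_weights=weights).fit_dataset(small_dataset)

    def test_fit_ensemble_weights_sum_to_one(self, small_model, small_split):
        _, test = small_split
        small_model.fit_ensemble_weights(test.features, test.labels, test.positions)
        assert sum(small_model.ensemble_weights_.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in small_model.ensemble_weights_.values())


class TestCountSteps:
    def test_end_to_end_recovery_on_fresh_recording(self, small_model):
        rec = gc.generate_walk(gc.GaitScenario(position="pocket", duration_s=600,
                                               step_freq_hz=1.8, seed=99))
        total, votes = small_model.count_steps(rec.accel)
        assert gc.step_accuracy(total, rec.truth.count) >= 90.0
        assert sum(votes.values()) == (600 * 30 - 60) // 30 + 1

    def test_single_window_recording(self, small_model):
        rec = gc.generate_walk(gc.GaitScenario(position="handheld", duration_s=2.0,
                                               step_freq_hz=1.8, seed=4))
        total, votes = small_model.count_steps(rec.accel)
        mag = gc.preprocess_accel(rec.accel)
        pred = small_model.predict(mag.v[None, :60],
                                   positions=[max(votes, key=votes.get)])[0]
        assert total == round(pred)

    def test_concatenated_recording_roughly_doubles(self, small_model):
        rec = gc.generate_walk(gc.GaitScenario(position="handbag", duration_s=120,
                                               step_freq_hz=2.0, seed=13))
        single, _ = small_model.count_steps(rec.accel)
        t2 = np.concatenate([rec.accel.t, rec.accel.t + rec.accel.t[-1] + 33])
        doubled = gc.AccelTrace(
            t=t2,
            x=np.tile(rec.accel.x, 2), y=np.tile(rec.accel.y, 2), z=np.tile(rec.accel.z, 2),
            position="handbag",
        )
        total2, _ = small_model.count_steps(doubled)
        max_window = 6  # one window's worth of steps at 2.4 Hz ceiling
        assert abs(total2 - 2 * single) <= max_window

    def test_too_short_trace_rejected(self, small_model):
        rec = gc.generate_walk(gc.GaitScenario(duration_s=1.0, step_freq_hz=1.8, seed=1))
        with pytest.raises(gc.InsufficientDataError):
            small_model.count_steps(rec.accel)


class TestFunctionalTrain:
    def test_train_wrapper_builds_requested_bank(self, small_split):
        train_set, _ = small_split
        specs = [
            gc.ModelSpec("random_forest", "classifier", hyperparams={"n_estimators": 20}),
            gc.ModelSpec("random_forest", "regressor", hyperparams={"n_estimators": 30}),
        ]
        model = gc.train(train_set, specs)
        for bank in model.regressors_.values():
            assert list(bank) == ["random_forest"]

    def test_train_wrapper_requires_one_classifier(self, small_split):
        train_set, _ = small_split
        with pytest.raises(ValueError):
            gc.train(train_set, [gc.ModelSpec("svm", "regressor")])
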