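"""Cascade structure: fold partitions, class-vector generation in both
augmentation modes, fusion, width law, depth selection, determinism."""

import numpy as np
import pytest

import celearn as ce
from celearn.cascade import _fold_assignment, augment, cv_class_vectors, fuse
from celearn.containers import FeatureTable, ProbabilityMatrix
from celearn.learners import LearnerSpec


def one_hot_pm(rows, nc=2):
    vals = np.zeros((len(rows), nc))
    vals[np.arange(len(rows)), np.asarray(rows) - 1] = 1.0
    return ProbabilityMatrix(values=vals, class_labels=np.arange(1, nc + 1))


class TestFoldAssignment:
    def test_partition_sizes_are_equal_when_divisible(self):
        labels = np.tile(np.arange(1, 5), 25)  # n=100, 4 classes
        fold_of = _fold_assignment(labels, 5, seed=0, n_classes=4)
        assert sorted(np.bincount(fold_of).tolist()) == [20] * 5

    def test_near_equal_when_not_divisible(self):
        labels = np.tile([1, 2], 51)[:101]
        fold_of = _fold_assignment(labels, 5, seed=1, n_classes=2)
        sizes = np.bincount(fold_of)
        assert sizes.max() - sizes.min() <= 1

    def test_training_parts_keep_two_classes_via_stratification(self):
        # 3 samples of class 2 among 60: a random split can strand them in
        # one fold; the training-part check must still hold afterwards
        labels = np.array([1] * 57 + [2] * 3)
        fold_of = _fold_assignment(labels, 3, seed=0, n_classes=2)
        for f in range(3):
            assert np.unique(labels[fold_of != f]).shape[0] == 2

    def test_impossible_fold_request_rejected(self):
        with pytest.raises(ValueError):
            _fold_assignment(np.array([1, 2]), 5, seed=0, n_classes=2)


class TestCvClassVectors:
    @pytest.mark.parametrize("mode", ["literal_k_minus_1", "out_of_fold"])
    def test_vectors_are_row_normalized(self, mode, blob_table):
        pm, models, fold_of = cv_class_vectors(
            LearnerSpec("softmax", {"n_iterations": 50}),
            blob_table, k=5, mode=mode, seed=0,
        )
        np.testing.assert_allclose(pm.values.sum(axis=1), 1.0, atol=1e-9)
        assert len(models) == 5
        assert fold_of.shape == (blob_table.n_samples,)

    def test_literal_mode_averages_exactly_k_minus_1_models(self, blob_table):
        """A sample's literal class vector must equal the hand-computed
        mean over the k-1 fold models whose training part contained it."""
        spec = LearnerSpec("softmax", {"n_iterations": 30})
        pm, models, fold_of = cv_class_vectors(
            spec, blob_table, k=4, mode="literal_k_minus_1", seed=2,
        )
        preds = [m.predict_proba(blob_table.features).values for m in models]
        for i in (0, 17, 101):
            in_training = [preds[f][i] for f in range(4) if f != fold_of[i]]
            assert len(in_training) == 3
            np.testing.assert_allclose(
                pm.values[i], np.mean(in_training, axis=0), atol=1e-12
            )

    def test_out_of_fold_mode_uses_the_heldout_model(self, blob_table):
        spec = LearnerSpec("softmax", {"n_iterations": 30})
        pm, models, fold_of = cv_class_vectors(
            spec, blob_table, k=4, mode="out_of_fold", seed=2,
        )
        preds = [m.predict_proba(blob_table.features).values for m in models]
        for i in (3, 55, 200):
            np.testing.assert_allclose(
                pm.values[i], preds[fold_of[i]][i], atol=1e-12
            )

    def test_leave_one_out_limit(self):
        table = ce.make_feature_table(
            ce.SynthSpec(n_samples=12, n_classes=2, n_features=4,
                         class_separation=6.0, seed=3)
        )
        pm, models, fold_of = cv_class_vectors(
            LearnerSpec("softmax", {"n_iterations": 20}),
            table, k=12, mode="out_of_fold", seed=0,
        )
        assert len(models) == 12
        assert sorted(fold_of.tolist()) == list(range(12))

    def test_both_modes_agree_on_argmax_for_separable_data(self, separable_table):
        spec = LearnerSpec("softmax", {"n_iterations": 100})
        lit, _, _ = cv_class_vectors(spec, separable_table, k=5,
                                     mode="literal_k_minus_1", seed=1)
        oof, _, _ = cv_class_vectors(spec, separable_table, k=5,
                                     mode="out_of_fold", seed=1)
        np.testing.assert_array_equal(lit.argmax_labels(), oof.argmax_labels())


class TestFuse:
    def test_identical_one_hot_inputs_are_a_fixed_point(self):
        pm = one_hot_pm([1, 2, 2])
        fused, labels = fuse([pm, pm, pm, pm])
        np.testing.assert_array_equal(fused.values, pm.values)
        np.testing.assert_array_equal(labels, [1, 2, 2])

    def test_ties_resolve_to_smallest_class_label(self):
        a = one_hot_pm([1])
        b = one_hot_pm([2])
        fused, labels = fuse([a, b, a, b])
        np.testing.assert_allclose(fused.values, [[0.5, 0.5]])
        assert labels.tolist() == [1]

    def test_matches_independent_elementwise_mean(self, rng):
        mats = []
        for _ in range(4):
            raw = rng.uniform(size=(6, 3))
            mats.append(ProbabilityMatrix(
                values=raw / raw.sum(axis=1, keepdims=True),
                class_labels=np.arange(1, 4),
            ))
        fused, _ = fuse(mats)
        expected = np.zeros((6, 3))
        for i in range(6):
            for j in range(3):
                expected[i, j] = sum(m.values[i, j] for m in mats) / 4
        np.testing.assert_allclose(fused.values, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share shape"):
            fuse([one_hot_pm([1, 2]), one_hot_pm([1])])


class TestAugment:
    def test_six_classes_append_24_columns(self, rng):
        n, d, nc = 10, 15, 6
        original = FeatureTable(features=rng.normal(size=(n, d)), n_classes=nc)
        vecs = [
            ProbabilityMatrix(values=np.full((n, nc), 1 / nc),
                              class_labels=np.arange(1, nc + 1))
            for _ in range(4)
        ]
        out = augment(original, vecs)
        assert out.n_features == d + 4 * nc == d + 24

    def test_block_slices_reproduce_inputs_exactly(self, rng):
        n, d, nc = 8, 10, 2
        original = FeatureTable(features=rng.normal(size=(n, d)), n_classes=nc)
        vecs = []
        for _ in range(4):
            raw = rng.uniform(size=(n, nc))
            vecs.append(ProbabilityMatrix(
                values=raw / raw.sum(axis=1, keepdims=True),
                class_labels=np.arange(1, nc + 1),
            ))
        out = augment(original, vecs)
        assert out.n_features == d + 4 * nc == 18
        np.testing.assert_array_equal(out.features[:, :d], original.features)
        for i, pm in enumerate(vecs):
            block = out.features[:, d + i * nc: d + (i + 1) * nc]
            np.testing.assert_array_equal(block, pm.values)

    def test_inconsistent_row_counts_rejected(self, rng):
        original = FeatureTable(features=rng.normal(size=(5, 3)), n_classes=2)
        with pytest.raises(ValueError, match="rows"):
            augment(original, [one_hot_pm([1, 2])])


class TestFitPredictCascade:
    def test_immediate_plateau_stops_after_one_plus_patience(
        self, separable_table, small_specs
    ):
        config = ce.CascadeConfig(k_folds=4, patience=3, max_layers=10,
                                  seed=0, learner_specs=small_specs)
        model = ce.fit_cascade(separable_table, config)
        assert model.layer_accuracies[0] == 1.0
        assert len(model.layers) == 1 + 3
        assert model.best_layer_index == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stopping_rule_bound(self, seed, small_specs):
        table = ce.make_feature_table(
            ce.SynthSpec(n_samples=240, n_classes=4, n_features=8,
                         class_separation=2.0, seed=seed)
        )
        config = ce.CascadeConfig(k_folds=4, patience=2, max_layers=6,
                                  seed=seed, learner_specs=small_specs)
        model = ce.fit_cascade(table, config)
        assert len(model.layers) <= model.best_layer_index + config.patience
        assert len(model.layers) <= config.max_layers
        assert 1 <= model.best_layer_index <= len(model.layers)
        # earliest argmax wins ties
        accs = model.layer_accuracies
        assert model.best_layer_index == int(np.argmax(accs)) + 1

    def test_layers_beyond_first_consume_constant_width(self, small_specs):
        """Recorded fold models of layer 2+ must have been fit on width
        d + 4 * NC (only the previous layer's vectors are concatenated)."""
        table = ce.make_feature_table(
            ce.SynthSpec(n_samples=300, n_classes=6, n_features=12,
                         class_separation=2.0, seed=5)
        )
        config = ce.CascadeConfig(k_folds=3, patience=1, max_layers=3,
                                  seed=0, learner_specs=small_specs)
        model = ce.fit_cascade(table, config)
        assert len(model.layers) >= 2
        for layer in model.layers[1:]:
            softmax_adapter = layer.fold_models[3][0]
            assert softmax_adapter.model.n_features == 12 + 4 * 6

    def test_seeded_end_to_end_determinism(self, small_specs):
        table = ce.make_feature_table(
            ce.SynthSpec(n_samples=200, n_classes=3, n_features=8,
                         class_separation=2.5, seed=9)
        )
        test = ce.make_feature_table(
            ce.SynthSpec(n_samples=80, n_classes=3, n_features=8,
                         class_separation=2.5, seed=1009)
        )
        config = ce.CascadeConfig(k_folds=3, patience=1, max_layers=3,
                                  seed=4, learner_specs=small_specs)
        l1, p1 = ce.predict_cascade(ce.fit_cascade(table, config), test)
        l2, p2 = ce.predict_cascade(ce.fit_cascade(table, config), test)
        assert np.array_equal(l1, l2)
        assert p1.values.tobytes() == p2.values.tobytes()

    def test_single_layer_prediction_is_fusion_of_layer_one(
        self, separable_table, small_specs
    ):
        config = ce.CascadeConfig(k_folds=3, patience=1, max_layers=1,
                                  seed=0, learner_specs=small_specs)
        model = ce.fit_cascade(separable_table, config)
        assert model.best_layer_index == 1
        labels, probs = ce.predict_cascade(model, separable_table)
        np.testing.assert_allclose(probs.values.sum(axis=1), 1.0, atol=1e-9)
        assert np.mean(labels == separable_table.labels) == 1.0

    def test_refit_full_self_consistency_on_separable_data(
        self, separable_table, small_specs
    ):
        config = ce.CascadeConfig(
            k_folds=3, patience=1, max_layers=2, seed=0,
            test_time_fold_handling="refit_full",
            learner_specs=small_specs,
        )
        model = ce.fit_cascade(separable_table, config)
        labels, _ = ce.predict_cascade(model, separable_table)
        best_acc = model.layer_accuracies[model.best_layer_index - 1]
        assert np.mean(labels == separable_table.labels) == best_acc == 1.0

    @pytest.mark.parametrize("mode", ["literal_k_minus_1", "out_of_fold"])
    def test_both_augmentation_modes_train_and_predict(self, mode, small_specs):
        table = ce.make_feature_table(
            ce.SynthSpec(n_samples=150, n_classes=3, n_features=6,
                         class_separation=3.0, seed=2)
        )
        config = ce.CascadeConfig(k_folds=3, patience=1, max_layers=2,
                                  seed=1, augmentation_mode=mode,
                                  learner_specs=small_specs)
        model = ce.fit_cascade(table, config)
        labels, probs = ce.predict_cascade(model, table.features)
        np.testing.assert_allclose(probs.values.sum(axis=1), 1.0, atol=1e-9)
        assert set(np.unique(labels)) <= {1, 2, 3}

    def test_wrong_prediction_width_rejected(self, separable_table,
                                             small_specs, rng):
        config = ce.CascadeConfig(k_folds=3, patience=1, max_layers=1,
                                  seed=0, learner_specs=small_specs)
        model = ce.fit_cascade(separable_table, config)
        with pytest.raises(ValueError, match="features"):
            ce.predict_cascade(model, rng.normal(size=(5, 99)))

    def test_config_dict_round_trip(self, small_specs):
        config = ce.CascadeConfig(k_folds=4, patience=2, max_layers=7,
                                  seed=13, augmentation_mode="out_of_fold",
                                  learner_specs=small_specs)
        again = ce.CascadeConfig.from_dict(config.to_dict())
        assert again == config
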