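"""Model tuning/training contracts and validation metrics."""

import numpy as np
import pandas as pd
import pytest

from ctpseg.modeling import (
    ALGORITHMS,
    FEATURE_SETS,
    ModelBundle,
    ModelConfig,
    compare_feature_sets,
    evaluate_on_validation,
    tune_and_train,
)
from ctpseg.patch_sampling import PatchMatrix


def _matrix(features, labels):
    n = len(labels)
    return PatchMatrix(
        features=features,
        labels=np.asarray(labels),
        provenance=pd.DataFrame({"study_id": ["s"] * n, "x": range(n), "y": 0, "z": 0}),
        feature_maps=("dt", "cbf", "mtt", "cbv"),
    )


def _separable_matrix(n_per_class=60, seed=0, signal_maps=(0, 1, 2, 3), spread=0.05):
    """Four Gaussian blobs, one per class, separated by a wide margin.

    ``signal_maps`` lists the 27-column blocks that carry the class signal;
    the remaining blocks are pure noise.
    """
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for cls in range(4):
        block = rng.normal(0.0, spread, size=(n_per_class, 108))
        for j in signal_maps:
            # orthogonal one-hot class signatures: class c lights up its own
            # group of 6 columns inside the block (separable one-vs-rest)
            cols = slice(j * 27 + cls * 6, j * 27 + (cls + 1) * 6)
            block[:, cols] += 1.0
        feats.append(block)
        labels.extend([cls] * n_per_class)
    return _matrix(np.vstack(feats), labels)


FAST = dict(random_candidates=2, grid_refine=False, cv_folds=2)


class TestTuneAndTrain:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_every_family_fits_a_separable_matrix_perfectly(self, algo):
        train = _separable_matrix(seed=0)
        val = _separable_matrix(seed=1)
        bundle = tune_and_train(train, ModelConfig(algorithm=algo, seed=0, **FAST))
        m = evaluate_on_validation(bundle, val)
        assert m["accuracy"] == 1.0
        assert m["dsc"][2] == 1.0 and m["dsc"][3] == 1.0
        assert m["roc_auc_macro"] == 1.0

    def test_lr_is_multinomial_over_four_classes(self):
        train = _separable_matrix(seed=0)
        bundle = tune_and_train(train, ModelConfig(algorithm="lr", seed=0, **FAST))
        assert sorted(bundle.model.classes_.tolist()) == [0, 1, 2, 3]
        assert bundle.model.predict_proba(train.features[:3]).shape == (3, 4)

    def test_same_seed_reproduces_hyperparameters(self):
        train = _separable_matrix(seed=0)
        cfg = ModelConfig(algorithm="xgb", seed=5, random_candidates=3, grid_refine=True, cv_folds=2)
        b1 = tune_and_train(train, cfg)
        b2 = tune_and_train(train, cfg)
        assert b1.best_params == b2.best_params

    def test_validation_rows_never_influence_hyperparameters(self):
        train = _separable_matrix(seed=0)
        cfg = ModelConfig(algorithm="rf", seed=2, **FAST)
        b1 = tune_and_train(train, cfg)
        # "validation" lives entirely outside tune_and_train; any validation
        # set, however corrupted, leaves the chosen hyperparameters unchanged
        _ = evaluate_on_validation(b1, _separable_matrix(seed=3))
        b2 = tune_and_train(train, cfg)
        _ = evaluate_on_validation(b2, _separable_matrix(seed=4, spread=5.0))
        assert b1.best_params == b2.best_params

    def test_single_class_training_rejected(self):
        m = _matrix(np.random.default_rng(0).random((30, 108)), [1] * 30)
        with pytest.raises(ValueError, match="two classes"):
            tune_and_train(m, ModelConfig(algorithm="lr", **FAST))

    def test_svm_searches_only_linear_and_poly_kernels(self):
        train = _separable_matrix(n_per_class=30, seed=0)
        bundle = tune_and_train(train, ModelConfig(algorithm="svm", seed=0, **FAST))
        assert bundle.best_params["estimator__kernel"] in ("linear", "poly")

    def test_bundle_roundtrips_without_metric_change(self, tmp_path):
        train = _separable_matrix(seed=0)
        val = _separable_matrix(seed=1)
        bundle = tune_and_train(train, ModelConfig(algorithm="xgb", seed=0, **FAST))
        before = evaluate_on_validation(bundle, val)
        p = tmp_path / "model.bundle"
        bundle.save(p)
        back = ModelBundle.load(p)
        after = evaluate_on_validation(back, val)
        assert before == after


class TestValidationMetrics:
    def test_perfect_predictions_score_one(self, xgb_bundle, train_validation):
        train, _ = train_validation
        m = evaluate_on_validation(xgb_bundle, train)
        # the phantom classes are separable, so training rows are fit perfectly
        assert m["dsc"][3] == pytest.approx(1.0)
        assert m["ji"][3] == pytest.approx(1.0)

    def test_all_one_class_prediction_dsc(self):
        # balanced 4-class truth, "core predicted everywhere":
        # DSC = 2n/(n + 4n) = 0.4 for core, 0 elsewhere
        from ctpseg.evaluation import dsc

        y = np.repeat([0, 1, 2, 3], 50)
        pred = np.full_like(y, 3)
        assert dsc(y == 3, pred == 3) == pytest.approx(0.4)
        assert dsc(y == 2, pred == 2) == 0.0

    def test_permuted_labels_give_chance_auc(self, xgb_bundle, train_validation):
        _, val = train_validation
        rng = np.random.default_rng(0)
        shuffled = PatchMatrix(
            features=val.features,
            labels=rng.permutation(val.labels),
            provenance=val.provenance,
            feature_maps=val.feature_maps,
        )
        m = evaluate_on_validation(xgb_bundle, shuffled)
        assert m["roc_auc_macro"] == pytest.approx(0.5, abs=0.05)

    def test_ji_below_dsc(self, xgb_bundle, train_validation):
        _, val = train_validation
        m = evaluate_on_validation(xgb_bundle, val)
        for cls in m["dsc"]:
            assert m["ji"][cls] <= m["dsc"][cls] + 1e-12


class TestCompareFeatureSets:
    def test_two_map_is_exact_column_subset(self, small_matrix):
        matrix, _ = small_matrix
        sub = matrix.select_maps(FEATURE_SETS["two_map"])
        np.testing.assert_array_equal(sub.features[:, :27], matrix.features[:, :27])
        np.testing.assert_array_equal(sub.features[:, 27:54], matrix.features[:, 27:54])
        assert sub.features.shape[1] == 54

    def test_four_map_wins_when_only_mtt_separates_penumbra(self):
        # classes 2 and 3 differ only in the MTT block: the two-map model
        # cannot tell them apart, the four-map model can
        train = _separable_matrix(seed=0, signal_maps=(2,))
        val = _separable_matrix(seed=1, signal_maps=(2,))
        out = compare_feature_sets(train, val, algorithm="xgb", seed=0, **FAST)
        acc2 = out["two_map"]["metrics"]["accuracy"]
        acc4 = out["four_map"]["metrics"]["accuracy"]
        assert acc4 > acc2 + 0.3
        assert acc4 == pytest.approx(1.0)

    def test_feature_sets_agree_when_extra_maps_carry_no_signal(self):
        train = _separable_matrix(seed=0, signal_maps=(0, 1))
        val = _separable_matrix(seed=1, signal_maps=(0, 1))
        out = compare_feature_sets(train, val, algorithm="lr", seed=0, **FAST)
        acc2 = out["two_map"]["metrics"]["accuracy"]
        acc4 = out["four_map"]["metrics"]["accuracy"]
        assert abs(acc4 - acc2) < 0.05
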