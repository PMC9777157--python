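"""Hybrid head: feature extraction, MinMax, PCA, SVM, end-to-end runs."""

import numpy as np
import pytest

from oagrade import cnn, dhl, nn
from oagrade.errors import ArchitectureError, ConfigurationError, InvalidInputError


class TestExtractFeatures:
    def test_shape_contract(self, trained_model, split_arrays):
        model, _ = trained_model
        x = split_arrays["x_test"]
        f = dhl.extract_features(model, x)
        assert f.shape == (len(x), 200)
        assert np.all(np.isfinite(f))

    def test_duplicate_images_identical_rows(self, trained_model, split_arrays):
        model, _ = trained_model
        x = np.repeat(split_arrays["x_test"][:1], 3, axis=0)
        f = dhl.extract_features(model, x)
        assert np.array_equal(f[0], f[1]) and np.array_equal(f[1], f[2])

    def test_unknown_layer_rejected(self, trained_model, split_arrays):
        model, _ = trained_model
        with pytest.raises(ArchitectureError):
            dhl.extract_features(model, split_arrays["x_test"][:1], layer="fc999")

    def test_matches_independent_layerwise_oracle(self):
        """Features equal a hand-rolled conv/pool/dense forward on a tiny clone."""
        from scipy.signal import correlate2d

        model = nn.Sequential(
            [
                nn.Conv2D(1, 2, name="c1"),
                nn.MaxPool2D("p1"),
                nn.Flatten("fl"),
                nn.Dense(8, 3, activation="relu", name="feat"),
                nn.Dense(3, 2, activation="softmax", name="out"),
            ],
            seed=5,
        )
        x = np.random.default_rng(0).random((2, 4, 4, 1)).astype(np.float32)
        got = dhl.extract_features(model, x, layer="feat")

        w1, b1 = model["c1"].params
        wd, bd = model["feat"].params
        for n in range(2):
            conv = np.stack(
                [
                    correlate2d(x[n, :, :, 0], w1[:, :, 0, co], mode="same") + b1[co]
                    for co in range(2)
                ],
                axis=-1,
            )
            conv = np.maximum(conv, 0.0)
            pooled = np.zeros((2, 2, 2))
            for i, j, c in np.ndindex(2, 2, 2):
                pooled[i, j, c] = conv[2 * i:2 * i + 2, 2 * j:2 * j + 2, c].max()
            feat = np.maximum(pooled.reshape(-1) @ wd + bd, 0.0)
            np.testing.assert_allclose(got[n], feat, atol=1e-5)


class TestMinMax:
    def test_basic_column(self):
        params = dhl.fit_minmax(np.array([[0.0], [5.0], [10.0]]))
        out = dhl.minmax_transform(np.array([[0.0], [5.0], [10.0]]), params)
        np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        params = dhl.fit_minmax(np.full((4, 2), 3.0))
        out = dhl.minmax_transform(np.full((4, 2), 3.0), params)
        assert np.all(out == 0.0)

    def test_test_values_may_exceed_range(self):
        params = dhl.fit_minmax(np.array([[0.0], [10.0]]))
        out = dhl.minmax_transform(np.array([[12.0]]), params)
        assert out[0, 0] == pytest.approx(1.2)

    def test_training_data_in_unit_interval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 10)) * 7 + 3
        out = dhl.minmax_transform(x, dhl.fit_minmax(x))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestPCA:
    def test_rank_one_single_component(self):
        base = np.random.default_rng(0).standard_normal(30)
        x = np.tile(base[:, None], (1, 200))
        model = dhl.fit_pca(x)
        assert model.n_components == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_needs_nearly_all_components(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5000, 200))
        model = dhl.fit_pca(x, 0.99)
        assert 195 <= model.n_components <= 199

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(2)
        x = rng.standard_normal((120, 20)) @ rng.standard_normal((20, 20))
        ours = dhl.fit_pca(x, 0.95)
        sk = SkPCA(n_components=0.95, svd_solver="full").fit(x)
        assert ours.n_components == sk.n_components_
        np.testing.assert_allclose(
            ours.explained_variance_ratio[: ours.n_components],
            sk.explained_variance_ratio_,
            rtol=1e-8,
        )

    def test_components_orthonormal_and_ratio_sums_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((300, 40))
        model = dhl.fit_pca(x)
        gram = model.components.T @ model.components
        np.testing.assert_allclose(gram, np.eye(40), atol=1e-8)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-10)

    def test_selection_rule_attains_target(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.standard_normal((60, 15)) * rng.random(15)
            model = dhl.fit_pca(x, 0.99)
            cum = np.cumsum(model.explained_variance_ratio)
            assert cum[model.n_components - 1] >= 0.99 - 1e-9
            if model.n_components > 1:
                assert cum[model.n_components - 2] < 0.99

    def test_bad_target_rejected(self):
        with pytest.raises(ConfigurationError):
            dhl.fit_pca(np.zeros((5, 3)), variance_target=1.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            dhl.fit_pca(np.zeros((1, 3)))

    def test_reduce_dimensions(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((50, 10))
        model = dhl.fit_pca(x, 0.5)
        reduced = dhl.pca_reduce(x, model)
        assert reduced.shape == (50, model.n_components)


class TestSVM:
    def test_rbf_kernel_unit_at_zero_distance(self):
        x = np.random.default_rng(0).random(7)
        assert dhl.rbf_kernel(x, x, gamma=0.001) == pytest.approx(1.0)

    def test_separated_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((40, 2)) + [0, 0]
        b = rng.standard_normal((40, 2)) + [30, 30]
        x = np.vstack([a, b])
        y = np.array([0] * 40 + [1] * 40)
        clf = dhl.fit_svm(x, y, dhl.SVMParams(C=1000, gamma=0.001))
        assert (dhl.svm_predict(clf, x) == y).mean() == 1.0

    def test_xor_fit_with_large_gamma(self):
        x = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        clf = dhl.fit_svm(x, y, dhl.SVMParams(C=1000, gamma=10.0))
        assert (dhl.svm_predict(clf, x) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            dhl.fit_svm(np.zeros((5, 2)), np.zeros(5))

    def test_scores_shape_binary_and_multiclass(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 3))
        y2 = rng.integers(0, 2, 30)
        y3 = rng.integers(0, 3, 30)
        y2[:2] = [0, 1]
        y3[:3] = [0, 1, 2]
        assert dhl.svm_scores(dhl.fit_svm(x, y2), x).shape == (30, 2)
        assert dhl.svm_scores(dhl.fit_svm(x, y3), x).shape == (30, 3)

    def test_bad_params_rejected(self):
        with pytest.raises(ConfigurationError):
            dhl.SVMParams(C=-1)


@pytest.fixture(scope="module")
def dhl_result(trained_model, split_arrays):
    model, _ = trained_model
    return dhl.run_dhl(
        model,
        split_arrays["x_train"], split_arrays["y_train"],
        split_arrays["x_test"], split_arrays["y_test"],
    )


class TestRunDhl:
    def test_confusion_rows_match_class_counts(self, dhl_result, split_arrays):
        cm = dhl_result.report.confusion_matrix
        y_test = split_arrays["y_test"]
        for g in range(5):
            assert cm[g].sum() == (y_test == g).sum()

    def test_above_chance_on_phantoms(self, dhl_result):
        assert dhl_result.report.accuracy / 100.0 > 0.2

    def test_feature_and_component_dims_logged(self, dhl_result):
        assert dhl_result.feature_dim == 200
        assert 1 <= dhl_result.n_components <= 200
        assert dhl_result.stage_log[0][0] == "extract-features"

    def test_leakage_guard_scaler_pca_fit_on_train_only(
        self, trained_model, split_arrays, dhl_result
    ):
        """Refitting scaler/PCA without any test rows changes nothing."""
        model, _ = trained_model
        f_train = dhl.extract_features(model, split_arrays["x_train"])
        scaler = dhl.fit_minmax(f_train)
        np.testing.assert_array_equal(scaler.min_, dhl_result.scaler.min_)
        np.testing.assert_array_equal(scaler.max_, dhl_result.scaler.max_)
        pca = dhl.fit_pca(dhl.minmax_transform(f_train, scaler))
        assert pca.n_components == dhl_result.pca.n_components
        np.testing.assert_array_equal(pca.eigenvalues, dhl_result.pca.eigenvalues)

    def test_binary_extremes_high_accuracy(self, trained_model, split_arrays):
        """Grades 0 vs 4 are maximally separated; hybrid head should excel."""
        model, _ = trained_model
        tr = np.isin(split_arrays["y_train"], [0, 4])
        te = np.isin(split_arrays["y_test"], [0, 4])
        y_tr = (split_arrays["y_train"][tr] == 4).astype(int)
        y_te = (split_arrays["y_test"][te] == 4).astype(int)
        result = dhl.run_dhl(
            model,
            split_arrays["x_train"][tr], y_tr,
            split_arrays["x_test"][te], y_te,
        )
        assert result.report.accuracy / 100.0 >= 0.9

    def test_beats_raw_cnn_softmax_at_fixed_seed(
        self, dhl_result, trained_model, split_arrays
    ):
        """Seeded regression mirroring the hybrid head's advantage over the CNN."""
        model, _ = trained_model
        pred = cnn.predict_classes(model, split_arrays["x_test"])
        cnn_acc = (pred == split_arrays["y_test"]).mean() * 100
        assert dhl_result.report.accuracy >= cnn_acc
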