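"""OPLS-DA: component policy, PLS equivalence oracle, diagnostics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from vibromap.core import ValidationError
from vibromap.opls import (
    NONE_LABEL,
    OPLSDA,
    OplsdaConfig,
    correlation_scaled_loadings,
    encode_dummy,
    hotelling_ellipse,
    q2_cross_validation,
)


def two_class_data(rng, n_per=30, m=20, sep=4.0, within=2.0, noise=0.3):
    """Separation along axis 0, within-class variation along axis 1.

    The within-class draw is centered per class so that, in-sample, it is
    exactly uncorrelated with class membership (a clean planted geometry).
    """
    X = rng.normal(0, noise, size=(2 * n_per, m))
    X[:n_per, 0] += sep
    v = rng.normal(0, within, 2 * n_per)
    v[:n_per] -= v[:n_per].mean()
    v[n_per:] -= v[n_per:].mean()
    X[:, 1] += v
    y = np.array(["red"] * n_per + ["blue"] * n_per)
    return X, y


class TestEncodeDummy:
    def test_rows_one_hot(self):
        Y = encode_dummy(["a", "b", "a"], ["a", "b"])
        assert Y.tolist() == [[1, 0], [0, 1], [1, 0]]

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            encode_dummy(["a", "a"], ["a"])

    def test_three_classes_row_sums(self):
        Y = encode_dummy(["a", "b", "c", "b"], ["a", "b", "c"])
        assert Y.shape == (4, 3)
        assert np.all(Y.sum(axis=1) == 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            encode_dummy(["a", "z"], ["a", "b"])


class TestFit:
    def test_planted_geometry_alignment(self, rng):
        X, y = two_class_data(rng, noise=0.05, sep=5.0, within=3.0)
        model = OPLSDA(n_ortho=1, classes=("blue", "red")).fit(X, y)
        w = model.W_[:, 0]
        sep_axis = np.zeros(20)
        sep_axis[0] = 1.0
        assert abs(w @ sep_axis) >= 0.99
        wo = model.W_o_[:, 0]
        within_axis = np.zeros(20)
        within_axis[1] = 1.0
        assert abs(wo @ within_axis) >= 0.99

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_component_policy(self, rng, n_classes):
        """C classes -> exactly C-1 predictive, at most C orthogonal."""
        n_per, m = 25, 30
        X = rng.normal(0, 0.3, size=(n_classes * n_per, m))
        for k in range(n_classes):
            X[k * n_per : (k + 1) * n_per, k] += 4.0
        X[:, n_classes + 1] += rng.normal(0, 2.0, n_classes * n_per)
        y = np.repeat([f"c{k}" for k in range(n_classes)], n_per)
        model = OPLSDA().fit(X, y)
        assert model.n_pred_ == n_classes - 1
        assert model.W_.shape[1] == n_classes - 1
        assert 0 <= model.n_ortho_ <= n_classes

    def test_no_within_class_structure_keeps_zero_orthogonal(self):
        # spectra exactly equal to their class mean: nothing to filter
        means = np.zeros((2, 10))
        means[0, 0] = 1.0
        means[1, 1] = 1.0
        X = np.repeat(means, 10, axis=0)
        y = np.repeat(["a", "b"], 10)
        model = OPLSDA().fit(X, y)
        assert model.n_ortho_ == 0

    def test_degenerate_x_rejected(self):
        X = np.ones((10, 8))
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValidationError):
            OPLSDA().fit(X, y)

    def test_score_orthogonality_and_reconstruction(self, rng):
        X, y = two_class_data(rng)
        model = OPLSDA(n_ortho=2, classes=("blue", "red")).fit(X, y)
        T, T_o = model.T_, model.T_o_
        for i in range(T.shape[1]):
            for j in range(T_o.shape[1]):
                rel = abs(T[:, i] @ T_o[:, j]) / (
                    np.linalg.norm(T[:, i]) * np.linalg.norm(T_o[:, j])
                )
                assert rel <= 1e-8
        # T P' + T_o P_o' + E reproduces centered X
        Xc = X - model.x_mean_
        _, _, E = model._filter_and_score(X)
        rec = T @ model.P_.T + T_o @ model.P_o_.T + E
        assert np.max(np.abs(rec - Xc)) <= 1e-10


class TestPredict:
    def test_training_set_reclassified_and_scores_match(self, rng):
        X, y = two_class_data(rng)
        model = OPLSDA(n_ortho=1, classes=("blue", "red")).fit(X, y)
        full = model.predict_full(X)
        assert np.max(np.abs(full.scores - model.T_)) <= 1e-10
        not_none = full.labels != NONE_LABEL
        assert np.array_equal(full.labels[not_none], y[not_none])
        # union outlier test at alpha=0.05: near-nominal flag rate
        assert np.mean(full.labels == NONE_LABEL) <= 0.10

    def test_zero_spectrum_is_none(self, rng):
        X, y = two_class_data(rng)
        X = np.abs(X) + 0.5  # tissue-like positive spectra
        model = OPLSDA(n_ortho=1, classes=("blue", "red")).fit(X, y)
        full = model.predict_full(np.zeros((1, X.shape[1])))
        assert full.labels[0] == NONE_LABEL

    def test_band_count_mismatch_rejected(self, rng):
        X, y = two_class_data(rng)
        model = OPLSDA(n_ortho=1, classes=("blue", "red")).fit(X, y)
        with pytest.raises(ValidationError):
            model.predict_full(rng.normal(size=(3, 5)))

    def test_pls_prediction_equivalence_oracle(self, rng):
        """Predicted dummy responses of OPLS (1 pred + k ortho) equal a
        plain (1+k)-component PLS regression on two-class data."""
        for trial in range(10):
            n, m = 40, 15
            X = rng.normal(size=(n, m))
            y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
            k = int(rng.integers(1, 4))
            model = OPLSDA(n_ortho=k, max_ortho=5, classes=("a", "b")).fit(X, y)
            pls = PLSRegression(n_components=1 + model.n_ortho_, scale=False).fit(
                X, encode_dummy(y, ["a", "b"])
            )
            Xte = rng.normal(size=(12, m))
            diff = np.max(np.abs(model.decision_function(Xte) - pls.predict(Xte)))
            assert diff <= 1e-8


class TestCorrelationScaledLoadings:
    def test_planted_band_high_null_band_low(self, rng):
        n_per, m = 100, 40
        X = rng.normal(1.0, 0.2, size=(2 * n_per, m))
        X[:n_per, 7] += 2.0  # discriminant band present only in class "red"
        y = np.array(["red"] * n_per + ["blue"] * n_per)
        model = OPLSDA(n_ortho=0, classes=("blue", "red")).fit(X, y)
        p = correlation_scaled_loadings(model, X)
        sign = np.sign(p[0, 7])
        assert abs(p[0, 7]) > 0.9
        # null bands: 0.2 is a per-band 95% bound at n=200
        null_bands = np.delete(np.arange(m), 7)
        assert np.quantile(np.abs(p[0, null_bands]), 0.95) <= 0.2
        assert np.all(p >= -1.0) and np.all(p <= 1.0)
        # sign convention: the band is more intensive on the side of "red"
        red_score_mean = model.T_[:n_per, 0].mean()
        assert sign == np.sign(red_score_mean)

    def test_zero_variance_band_zero_with_warning(self, rng):
        X, y = two_class_data(rng)
        X[:, 5] = 2.0
        model = OPLSDA(n_ortho=0, classes=("blue", "red")).fit(X, y)
        with pytest.warns(UserWarning, match="zero-variance"):
            p = correlation_scaled_loadings(model, X)
        assert p[0, 5] == 0.0


class TestQ2:
    def test_separable_data_high_q2(self, rng):
        X, y = two_class_data(rng, noise=0.05, sep=6.0, within=0.5)
        q = q2_cross_validation(X, y, class_names=("blue", "red"))
        assert q.q2_cum >= 0.9
        assert q.q2_cum <= q.r2y <= 1.0

    def test_permuted_labels_low_q2(self, rng):
        n, m = 200, 30
        X = rng.normal(size=(n, m))
        X[: n // 2, 0] += 3.0
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        y_perm = rng.permutation(y)
        q = q2_cross_validation(X, y_perm, class_names=("a", "b"))
        assert q.q2_cum <= 0.2

    def test_fold_losing_class_reports_fold(self, rng):
        X = rng.normal(size=(14, 10))
        X[:7, 0] += 3
        # class "b" occupies exactly the rows of fold 0 (interleaved % 7)
        y = np.array(["a"] * 14, dtype=object)
        y[[0, 7]] = "b"
        with pytest.raises(ValidationError, match="fold 0"):
            q2_cross_validation(X, y, config=OplsdaConfig(n_ortho=0), class_names=("a", "b"))


class TestHotelling:
    def test_isotropic_scores_axes_equal(self, rng):
        T = rng.normal(size=(4000, 2))
        e = hotelling_ellipse(T)
        assert abs(e.semi_axes[0] - e.semi_axes[1]) / e.semi_axes[0] < 0.1

    def test_scaling_equivariance(self, rng):
        T = rng.normal(size=(50, 2)) @ np.array([[2.0, 0.5], [0.0, 1.0]])
        e1 = hotelling_ellipse(T)
        e2 = hotelling_ellipse(10.0 * T)
        assert np.allclose(e2.semi_axes, 10.0 * e1.semi_axes)
        assert np.allclose(e2.t2, e1.t2)

    def test_critical_value_formula(self, rng):
        T = rng.normal(size=(100, 2))
        e = hotelling_ellipse(T, alpha=0.05)
        expected = 2 * 99 / 98 * stats.f.ppf(0.95, 2, 98)
        assert e.t2_crit == pytest.approx(expected)

    def test_coverage_short_simulation(self, rng):
        cov = [
            np.mean((e := hotelling_ellipse(rng.normal(size=(100, 2)))).t2 <= e.t2_crit)
            for _ in range(300)
        ]
        assert np.mean(cov) == pytest.approx(0.95, abs=0.015)

    def test_singular_covariance_rejected(self):
        T = np.ones((10, 2))
        with pytest.raises(ValidationError):
            hotelling_ellipse(T)
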