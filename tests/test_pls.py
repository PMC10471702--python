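import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metabodiverge.pls import (
    coefficient_ci,
    fit_pls,
    fit_plsda,
    q2_statistic,
    vip_scores,
)


def _random_xy(seed, n=12, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_single_proportional_column_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = x[:, None]
        y = 3.0 * x + 1.0
        model = fit_pls(X, y, 1)
        pred = model.predict(X)
        np.testing.assert_allclose(pred, y, atol=1e-10)
        assert model.coefficients[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_scorespace_and_coefficient_predictions_agree(self, seed):
        X, y = _random_xy(seed)
        model = fit_pls(X, y, 3)
        from_scores = model.y_mean + model.scores @ model.y_loadings
        from_coefs = model.predict(X)
        np.testing.assert_allclose(from_scores, from_coefs, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_full_rank_pls_equals_ols(self, seed):
        X, y = _random_xy(seed, n=10, p=5)
        model = fit_pls(X, y, 5)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_scores_are_mutually_orthogonal(self, seed):
        X, y = _random_xy(seed, n=15, p=8)
        model = fit_pls(X, y, 5)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_zero_variance_response_rejected(self):
        X, _ = _random_xy(1)
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(len(X)), 1)

    def test_component_count_beyond_rank_rejected(self):
        X, y = _random_xy(2, n=6, p=10)
        with pytest.raises(ValueError):
            fit_pls(X, y, 8)


class TestVip:
    @pytest.mark.parametrize("seed", range(5))
    def test_mean_squared_vip_is_one(self, seed):
        X, y = _random_xy(seed, n=14, p=7)
        model = fit_pls(X, y, 3)
        assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_one_component_closed_form(self):
        X, y = _random_xy(7, n=12, p=4)
        model = fit_pls(X, y, 1)
        w = model.x_weights[:, 0]
        expected = np.sqrt(4) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(model.vip, expected, atol=1e-12)

    def test_identical_predictors_share_unit_vip(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=16)
        X = np.column_stack([x, x, x])
        y = 2.0 * x + rng.normal(0, 0.1, size=16)
        model = fit_pls(X, y, 1)
        np.testing.assert_allclose(model.vip, np.ones(3), atol=1e-10)

    def test_matches_literal_summation_formula(self):
        X, y = _random_xy(9, n=15, p=3)
        model = fit_pls(X, y, 2)
        p = 3
        ssy = model.ssy_per_component
        literal = np.zeros(p)
        for j in range(p):
            acc = 0.0
            for a in range(model.n_components):
                w = model.x_weights[:, a]
                acc += ssy[a] * (w[j] / np.linalg.norm(w)) ** 2
            literal[j] = np.sqrt(p * acc / ssy.sum())
        np.testing.assert_allclose(model.vip, literal, atol=1e-12)


class TestPlsda:
    def test_perfect_separation_gives_zero_training_error(self):
        rng = np.random.default_rng(10)
        labels = np.repeat(["H", "L"], 10)
        X = np.column_stack([(labels == "H").astype(float), rng.normal(size=(20, 3))])
        model = fit_plsda(X, labels, 2)
        assert (model.predict_class(X) == labels).all()

    def test_class_coding_symmetry(self):
        rng = np.random.default_rng(11)
        labels = np.repeat(["H", "L"], 12)
        X = rng.normal(size=(24, 5))
        X[:, 0] += 1.2 * (labels == "H")
        base = fit_plsda(X, labels, 2).predict_class(X)
        # renaming flips which class carries code 1; decisions must map over
        flipped_labels = np.where(labels == "H", "Z", "A")  # H now sorts last
        flipped = fit_plsda(X, flipped_labels, 2).predict_class(X)
        assert ((flipped == "Z") == (base == "H")).all()

    def test_uninformative_features_misclassify_at_chance(self):
        rng = np.random.default_rng(12)
        errs = 0
        trials = 0
        for _ in range(30):
            labels = np.repeat(["H", "L"], 12)
            X_train = rng.normal(size=(24, 4))
            X_test = rng.normal(size=(24, 4))
            test_labels = rng.permutation(labels)
            model = fit_plsda(X_train, labels, 2)
            errs += int((model.predict_class(X_test) != test_labels).sum())
            trials += 24
        lo = stats.binom.ppf(0.0005, trials, 0.5)
        hi = stats.binom.ppf(0.9995, trials, 0.5)
        assert lo <= errs <= hi

    def test_single_class_rejected(self):
        X, _ = _random_xy(13)
        with pytest.raises(ValueError):
            fit_plsda(X, ["H"] * len(X), 1)


class TestCoefficientCi:
    def test_exact_relationship_gives_zero_width(self):
        x = np.linspace(-1, 1, 21)
        y = 2.5 * x
        ci, _ = coefficient_ci(x[:, None], y, 1, inner_folds=7)
        assert ci[0, 1] - ci[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert ci[0, 0] == pytest.approx(2.5)

    def test_interval_matches_literal_jackknife_formula(self):
        X, y = _random_xy(14, n=21, p=4)
        rng = np.random.default_rng(15)
        ci, b_seg = coefficient_ci(X, y, 2, inner_folds=7, rng=rng)
        b_full = fit_pls(X, y, 2).coefficients
        B = np.asarray(b_seg)
        m = B.shape[0]
        se = np.sqrt((m - 1) / m * ((B - b_full) ** 2).sum(axis=0))
        tq = stats.t.ppf(0.975, df=m - 1)
        np.testing.assert_allclose(ci[:, 0], b_full - tq * se, atol=1e-12)
        np.testing.assert_allclose(ci[:, 1], b_full + tq * se, atol=1e-12)
        # exclusion rule equivalence
        excl = (ci[:, 0] > 0) | (ci[:, 1] < 0)
        np.testing.assert_array_equal(excl, np.abs(b_full) > tq * se)

    def test_noise_exclusion_rate_near_nominal(self):
        """Under a pure-noise response ~5% of true-zero coefficients should
        be excluded at the 95% level (wide binomial tolerance)."""
        rng = np.random.default_rng(42)
        excl, tot = 0, 0
        for _ in range(200):
            X = rng.normal(size=(21, 3))
            y = rng.normal(size=21)
            ci, _ = coefficient_ci(X, y, 1, inner_folds=7, rng=rng)
            excl += int(((ci[:, 0] > 0) | (ci[:, 1] < 0)).sum())
            tot += 3
        assert 0.01 < excl / tot < 0.10

    def test_too_few_segments_rejected(self):
        X, y = _random_xy(16)
        with pytest.raises(ValueError):
            coefficient_ci(X, y, 1, inner_folds=1)


class TestQ2:
    def test_point_examples(self):
        assert q2_statistic([1, 2, 3], [1, 2, 3], 2.0) == pytest.approx(1.0)
        assert q2_statistic([1, 2, 3], [2, 2, 2], 2.0) == pytest.approx(0.0)
        assert q2_statistic([1, 2, 3], [1, 1, 3], 2.0) == pytest.approx(0.5)

    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
        st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=8)
        pred = y + rng.normal(0, 0.5, size=8)
        base = q2_statistic(y, pred, y.mean())
        moved = q2_statistic(scale * y + shift, scale * pred + shift, scale * y.mean() + shift)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            q2_statistic([2.0, 2.0], [1.0, 3.0], 2.0)
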