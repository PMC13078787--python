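"""Linear Raman-proteome correspondence: fitting, LOOCV, permutation test."""

import numpy as np
import pytest

import stoichiomap as sm
from stoichiomap.correspondence import fit_B, RamanProteomeRegression


def _exact_system(m=8, K=4, n=30, seed=0):
    """P_hat generated exactly as design @ B_true^T with a full-rank design."""
    rng = np.random.default_rng(seed)
    R = rng.normal(size=(m, K))
    B_true = rng.normal(size=(n, K + 1))
    design = np.column_stack([np.ones(m), R])
    return design @ B_true.T, R, B_true


class TestFitB:
    def test_exact_linear_system_recovered(self):
        P_hat, R, B_true = _exact_system()
        model = fit_B(P_hat, R, n_axes=4)
        np.testing.assert_allclose(model.B_, B_true, atol=1e-8)

    def test_constant_proteome_gives_pure_intercept(self):
        rng = np.random.default_rng(1)
        R = rng.normal(size=(6, 3))
        P_hat = np.tile([2.0, 5.0, 7.0], (6, 1))
        model = fit_B(P_hat, R, n_axes=3)
        np.testing.assert_allclose(model.B_[:, 0], [2.0, 5.0, 7.0], atol=1e-10)
        np.testing.assert_allclose(model.B_[:, 1:], 0.0, atol=1e-10)

    def test_underdetermined_fit_is_minimum_norm_with_zero_residual(self):
        # 5 training rows, 6 unknowns (intercept + 5 axes): verify against
        # the pseudo-inverse oracle
        rng = np.random.default_rng(2)
        R = rng.normal(size=(5, 5))
        P_hat = rng.normal(size=(5, 12))
        model = fit_B(P_hat, R, n_axes=5)
        design = np.column_stack([np.ones(5), R])
        oracle = (np.linalg.pinv(design) @ P_hat).T
        np.testing.assert_allclose(model.B_, oracle, atol=1e-8)
        np.testing.assert_allclose(design @ model.B_.T, P_hat, atol=1e-8)

    def test_too_few_axes_in_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_B(np.zeros((4, 2)), np.zeros((4, 2)), n_axes=3)


@pytest.fixture(scope="module")
def model():
    P_hat, R, _ = _exact_system()
    return fit_B(P_hat, R, n_axes=4), P_hat, R


class TestPredict:
    def test_zero_vector_returns_intercept(self, model):
        fitted, _, _ = model
        np.testing.assert_allclose(fitted.predict(np.zeros(4)), fitted.B_[:, 0])

    def test_training_rows_reproduced_for_exact_fit(self, model):
        fitted, P_hat, R = model
        np.testing.assert_allclose(fitted.predict(R), P_hat, atol=1e-8)

    def test_affine_identity(self, model):
        fitted, _, _ = model
        rng = np.random.default_rng(3)
        r1, r2 = rng.normal(size=4), rng.normal(size=4)
        lhs = fitted.predict(r1) + fitted.predict(r2) - fitted.predict(np.zeros(4))
        np.testing.assert_allclose(lhs, fitted.predict(r1 + r2), atol=1e-8)

    def test_length_mismatch_rejected(self, model):
        fitted, _, _ = model
        with pytest.raises(ValueError):
            fitted.predict(np.zeros(3))


class TestDistance:
    @pytest.mark.parametrize(
        "metric", ["euclidean_sq", "manhattan", "cosine_dist", "one_minus_pearson"]
    )
    def test_identical_profiles_are_at_zero(self, metric, rng):
        x = rng.normal(size=10)
        assert sm.distance(x, x, metric) == pytest.approx(0, abs=1e-12)

    def test_orthogonal_unit_vectors(self):
        x, y = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert sm.distance(x, y, "euclidean_sq") == pytest.approx(2.0)
        assert sm.distance(x, y, "cosine_dist") == pytest.approx(1.0)

    def test_cosine_scale_invariance(self, rng):
        x, y = rng.random(8) + 0.1, rng.random(8) + 0.1
        assert sm.distance(x, y, "cosine_dist") == pytest.approx(
            sm.distance(x, 2.0 * y, "cosine_dist")
        )

    def test_zero_vector_rejected_for_angular_metrics(self):
        with pytest.raises(ValueError):
            sm.distance(np.zeros(3), np.ones(3), "cosine_dist")


class TestLoocv:
    def test_exactness_oracle_on_noiseless_linear_data(self):
        P_hat, R, _ = _exact_system(m=10, K=4, n=40)
        report = sm.loocv(P_hat, R, n_axes=4)
        scale = np.linalg.norm(P_hat)
        assert report.overall["euclidean_sq"] < (1e-6 * scale) ** 2

    def test_condition_order_exchangeable(self):
        P_hat, R, _ = _exact_system(m=7, K=3, n=20, seed=5)
        P_hat += np.random.default_rng(6).normal(size=P_hat.shape)  # break exactness
        a = sm.loocv(P_hat, R, n_axes=3)
        perm = np.random.default_rng(7).permutation(7)
        b = sm.loocv(P_hat[perm], R[perm], n_axes=3)
        assert a.overall["euclidean_sq"] == pytest.approx(b.overall["euclidean_sq"])

    def test_overall_is_sum_of_per_condition(self):
        P_hat, R, _ = _exact_system(m=6, K=2, n=15, seed=8)
        report = sm.loocv(P_hat, R, n_axes=2, metrics=("euclidean_sq", "manhattan"))
        for met in report.overall:
            assert report.overall[met] == pytest.approx(report.per_condition[met].sum())

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            sm.loocv(np.zeros((2, 3)), np.zeros((2, 2)), n_axes=1)


class TestPermutationTest:
    def test_permuted_copy_not_better_than_matching_sigma(self, rng):
        P_hat = rng.random((6, 10)) + 0.5
        perm = np.array([1, 2, 3, 4, 5, 0])
        preds = P_hat[perm]
        p = sm.permutation_test(P_hat, preds, n_permutations=500, seed=1)
        # the matching permutation scores 0 <= observed, so p > 1/(n+1)
        assert p > 1 / 501

    def test_pvalue_bounds(self, rng):
        P_hat = rng.random((5, 8))
        preds = rng.random((5, 8))
        p = sm.permutation_test(P_hat, preds, n_permutations=200, seed=2)
        assert 1 / 201 <= p <= 1.0

    def test_linked_synthetic_data_is_significant(self, small_analysis):
        report = sm.loocv(
            small_analysis["P_hat"],
            small_analysis["R_hat"],
            n_axes=4,
            n_permutations=1000,
            seed=4,
        )
        assert report.permutation_p["euclidean_sq"] <= 0.01


class TestNormalizedCoefficients:
    def test_proportional_rows_share_a_coordinate(self):
        model = RamanProteomeRegression(n_axes=2)
        model.B_ = np.array([[2.0, 4.0, 6.0], [1.0, 2.0, 3.0]])
        omega_b, kept, excluded = model.normalized_coefficients()
        np.testing.assert_allclose(omega_b[0], omega_b[1])
        np.testing.assert_allclose(omega_b[0], [2.0, 3.0])
        assert excluded.size == 0

    def test_zero_intercept_excluded_not_nan(self):
        model = RamanProteomeRegression(n_axes=1)
        model.B_ = np.array([[1.0, 2.0], [0.0, 5.0], [3.0, 6.0]])
        omega_b, kept, excluded = model.normalized_coefficients()
        assert list(excluded) == [1]
        assert np.all(np.isfinite(omega_b))

    def test_conserved_group_collapses_to_one_point(self):
        # group rows b_i = a_i * (1, c1, c2, ...) in an exact system
        rng = np.random.default_rng(9)
        m, K = 7, 6
        R = rng.normal(size=(m, K))
        c = rng.normal(size=K)
        amps = rng.lognormal(size=10)
        B_true = np.column_stack([amps, amps[:, None] * c[None, :]])
        design = np.column_stack([np.ones(m), R])
        P_hat = design @ B_true.T
        model = fit_B(P_hat, R, n_axes=K)
        omega_b, kept, _ = model.normalized_coefficients()
        np.testing.assert_allclose(omega_b, np.tile(c, (10, 1)), atol=1e-8)

    def test_omega_b_invariant_to_protein_scaling(self):
        P_hat, R, _ = _exact_system(m=8, K=3, n=12, seed=10)
        base, _, _ = fit_B(P_hat, R, n_axes=3).normalized_coefficients()
        scaled, _, _ = fit_B(P_hat * 7.5, R, n_axes=3).normalized_coefficients()
        np.testing.assert_allclose(scaled, base, atol=1e-8)


class TestCoefficientProportionality:
    def test_exact_proportionality_recovered(self):
        b0 = np.linspace(1, 5, 20)
        B = np.column_stack([b0, 2.0 * b0, -0.5 * b0])
        slopes, r2 = sm.coefficient_proportionality(B, np.arange(20))
        np.testing.assert_allclose(slopes, [2.0, -0.5])
        np.testing.assert_allclose(r2, 1.0)

    def test_random_coefficients_fit_poorly(self, rng):
        worst = max(
            sm.coefficient_proportionality(rng.normal(size=(50, 3)), np.arange(50))[1].max()
            for _ in range(20)
        )
        assert worst < 0.5

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sm.coefficient_proportionality(np.ones((5, 3)), [0, 1])

    def test_planted_core_shows_proportionality_on_growth_axis(self, small_analysis):
        report = sm.loocv(small_analysis["P_hat"], small_analysis["R_hat"], n_axes=4)
        core = np.flatnonzero(small_analysis["truth"]["group"].to_numpy() == "core")
        _, r2 = sm.coefficient_proportionality(report.B_average, core)
        # the planted core follows a one-dimensional growth law, so the
        # proportionality is strong on the growth-dominated leading axis
        assert r2[0] >= 0.9
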