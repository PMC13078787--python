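"""Theta construction and diagnostics, d-g proportionality, subsampling."""

import numpy as np
import pytest

import stoichiomap as sm
from stoichiomap.comparison import theta_from_dataset, theta_report


def _coords(n=60, m=6, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n, m - 1))
    trivial = np.ones(n) / np.sqrt(n)
    return coords, trivial


class TestComputeTheta:
    def test_identical_coordinates_give_identity(self):
        coords, _ = _coords()
        trivial = np.ones(coords.shape[0])  # augmented first columns match
        theta = sm.compute_theta(coords, trivial, coords)
        np.testing.assert_allclose(theta, np.eye(coords.shape[1] + 1), atol=1e-8)

    def test_exact_rotation_recovered(self):
        # omega_b constructed as an exact rotation of the csLE axes (leaving
        # the constant axis fixed) -> Theta is exactly that rotation
        coords, _ = _coords(m=5, seed=1)
        trivial = np.ones(coords.shape[0])
        R_block = sm.haar_orthogonal(4, seed=2)
        omega_b = coords @ R_block
        theta = sm.compute_theta(coords, trivial, omega_b)
        expected = np.eye(5)
        expected[1:, 1:] = R_block
        np.testing.assert_allclose(theta, expected, atol=1e-8)

    def test_rank_deficient_coordinates_rejected(self):
        coords, trivial = _coords(m=4)
        coords[:, 2] = coords[:, 1]
        with pytest.raises(ValueError, match="rank-deficient"):
            sm.compute_theta(coords, trivial, coords)

    def test_row_misalignment_rejected(self):
        coords, trivial = _coords()
        with pytest.raises(ValueError):
            sm.compute_theta(coords, trivial, coords[:-1])

    def test_pipeline_theta_beats_haar_null(self, small_analysis):
        theta = theta_from_dataset(
            small_analysis["proteome"],
            small_analysis["scores"],
            small_analysis["processed"].condition,
            small_analysis["conditions"]["condition_id"].to_numpy(),
        )
        rep = theta_report(theta, n_null=100, seed=5)
        assert rep.percentile >= 95.0


class TestHaarOrthogonal:
    def test_orthogonality_and_unit_columns(self):
        Q = sm.haar_orthogonal(12, seed=3)
        np.testing.assert_allclose(Q.T @ Q, np.eye(12), atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(Q, axis=0), 1.0, atol=1e-10)

    def test_first_entry_moments_match_haar(self):
        # for Haar-distributed Q at m=3, Q11 has mean 0 and variance 1/3
        rng = np.random.default_rng(6)
        draws = np.array([sm.haar_orthogonal(3, rng)[0, 0] for _ in range(2000)])
        assert abs(draws.mean()) < 0.03
        assert draws.var() == pytest.approx(1 / 3, abs=0.03)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            sm.haar_orthogonal(1)


class TestClosenessScore:
    def test_identity_scores_one(self):
        assert sm.closeness_score(np.eye(7)) == pytest.approx(1.0, abs=1e-12)

    def test_reversal_permutation_scores_minus_one(self):
        # weighted Pearson of pairs (i, m+1-i) is exactly -1; checked by
        # hand at m=3: points (1,3), (2,2), (3,1) with unit weights
        Q = np.fliplr(np.eye(3))
        assert sm.closeness_score(Q) == pytest.approx(-1.0, abs=1e-12)

    def test_haar_null_scatters_below_one_around_zero(self):
        rng = np.random.default_rng(7)
        scores = np.array(
            [sm.closeness_score(sm.haar_orthogonal(15, rng)) for _ in range(1000)]
        )
        assert scores.max() < 1.0
        assert abs(scores.mean()) < 0.05

    def test_nonidentity_permutation_scores_below_one(self):
        P = np.eye(5)[[1, 0, 2, 4, 3]]
        assert sm.closeness_score(P) < 1.0

    def test_one_by_one_rejected(self):
        with pytest.raises(ValueError):
            sm.closeness_score(np.eye(1))


class TestOffdiagonalProfile:
    def test_identity_mass_arrives_at_last_step(self):
        curve = sm.offdiagonal_profile(np.eye(6))
        np.testing.assert_allclose(curve[:-1], 0.0, atol=1e-12)
        assert curve[-1] == pytest.approx(6.0)

    def test_total_mass_is_m_for_any_orthogonal(self):
        Q = sm.haar_orthogonal(9, seed=8)
        assert sm.offdiagonal_profile(Q)[-1] == pytest.approx(9.0, abs=1e-10)

    def test_antidiagonal_first_band_mass(self):
        # reversal permutation at m=4: entries (1,4) and (4,1) carry mass 2
        Q = np.fliplr(np.eye(4))
        curve = sm.offdiagonal_profile(Q)
        assert curve[0] == pytest.approx(2.0)


class TestLeadingSubmatrixProfile:
    def test_identity_curve_counts_diagonal(self):
        np.testing.assert_allclose(
            sm.leading_submatrix_profile(np.eye(5)), np.arange(1, 6, dtype=float)
        )

    def test_final_value_is_m(self):
        Q = sm.haar_orthogonal(8, seed=9)
        assert sm.leading_submatrix_profile(Q)[-1] == pytest.approx(8.0, abs=1e-10)

    def test_block_rotation_first_value(self):
        th = 0.7
        Q = np.eye(3)
        Q[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        assert sm.leading_submatrix_profile(Q)[0] == pytest.approx(np.cos(th) ** 2)


class TestThetaReport:
    def test_identity_beats_every_haar_draw(self):
        rep = theta_report(np.eye(8), n_null=300, seed=10)
        assert rep.closeness == pytest.approx(1.0, abs=1e-12)
        assert rep.percentile == 100.0
        np.testing.assert_allclose(rep.leading_identity, np.arange(1, 9, dtype=float))

    def test_hadamard_square_mass_constraints(self):
        Q = sm.haar_orthogonal(6, seed=11)
        W = Q * Q
        np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)
        assert W.sum() == pytest.approx(6.0, abs=1e-10)

    def test_non_orthogonal_input_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            theta_report(np.ones((4, 4)), n_null=10)


class TestDGProportionality:
    def test_fully_conserved_uniform_proteome_has_zero_residuals(self):
        n, m = 200, 9
        d = np.full(n, float(n))
        g = np.full(n, np.sqrt(m))
        rep = sm.d_g_proportionality(d, g, m)
        assert rep.slope == pytest.approx(n / np.sqrt(m))
        np.testing.assert_allclose(rep.residuals, 0.0, atol=1e-6 * n)

    def test_equal_growth_rate_data_has_small_residuals(self):
        # chemostat-like study: every condition at the same growth rate
        rng = np.random.default_rng(12)
        m, n = 8, 300
        pattern = rng.random(m) * 0.1 + 1.0  # near-uniform conditions
        P = rng.lognormal(sigma=0.3, size=n)[:, None] * pattern[None, :]
        P *= rng.lognormal(sigma=0.05, size=(n, m))
        graph = sm.cosine_matrix(P)
        g = sm.generality(P)
        rep = sm.d_g_proportionality(graph.degree, g, m)
        rel = np.abs(rep.residuals) / np.median(graph.degree)
        assert np.quantile(rel, 0.95) < 0.05

    def test_growth_structured_data_residuals_track_growth_rate(self, small_analysis):
        proteome = small_analysis["proteome"]
        graph = sm.cosine_matrix(proteome)
        g = sm.generality(proteome)
        mu = small_analysis["conditions"].set_index("condition_id")["growth_rate"]
        argmax = proteome.idxmax(axis=1)
        rep = sm.d_g_proportionality(
            graph.degree, g.to_numpy(), proteome.shape[1], mu.loc[argmax].to_numpy()
        )
        assert rep.spearman_p < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.d_g_proportionality(np.ones(3), np.ones(4), 5)


class TestSubsampleConditions:
    def test_full_size_matches_direct_analysis(self, small_analysis):
        proc = small_analysis["processed"]
        out = sm.subsample_conditions(
            small_analysis["proteome"], proc.intensities, proc.condition,
            sizes=[8], reps=1, seed=0, n_null=20,
        )
        theta = theta_from_dataset(
            small_analysis["proteome"], small_analysis["scores"],
            proc.condition, small_analysis["conditions"]["condition_id"].to_numpy(),
        )
        assert out["closeness"].iloc[0] == pytest.approx(sm.closeness_score(theta), abs=1e-8)

    def test_seed_reproducible(self, small_analysis):
        proc = small_analysis["processed"]
        kwargs = dict(sizes=[4], reps=2, seed=5, n_null=10)
        a = sm.subsample_conditions(
            small_analysis["proteome"], proc.intensities, proc.condition, **kwargs
        )
        b = sm.subsample_conditions(
            small_analysis["proteome"], proc.intensities, proc.condition, **kwargs
        )
        np.testing.assert_allclose(a["closeness"], b["closeness"])

    def test_undersized_subset_rejected(self, small_analysis):
        proc = small_analysis["processed"]
        with pytest.raises(ValueError):
            sm.subsample_conditions(
                small_analysis["proteome"], proc.intensities, proc.condition,
                sizes=[2], reps=1,
            )
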