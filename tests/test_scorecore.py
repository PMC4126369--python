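"""Score contributions, pair weights, variance paths and test statistics."""

import numpy as np
import pytest
from scipy import stats

from gdtpoly import design, nuisance, scorecore, simulator
from gdtpoly.pedio import FamilySample
from helpers import random_family, weighted_cov_oracle


def two_member_sample(x=(1.0, 0.0), unrelated=True):
    pi = np.eye(2) if unrelated else np.ones((2, 2))
    return FamilySample(
        "1", ["1", "2"], np.array([1, 2]), 2, kin2=pi.astype(float),
        x2=np.array(x, dtype=float), pi2=pi.astype(float),
        x1=np.array(x, dtype=float), pi1=pi.astype(float),
    )


def stub_fit(K, slopes):
    """A nuisance fit with prescribed per-category slopes on x2."""
    spec = design.one_locus(K=K, var="x2", prefix="a")
    p = (K - 1) + len(spec.labels)
    theta = np.zeros(p)
    theta[K - 1:] = slopes
    return nuisance.PolytomousFit(
        spec=spec, param_names=("?",) * p, theta=theta, loglik=0.0,
        converged=True, n_iter=0, n_obs=0,
        obs_scores=np.zeros((0, p)), information=np.eye(p),
    )


class TestScores:
    def test_hand_computed_double_sum(self):
        """K=2, n=4: one affected with x=1 against {1/2, 0, 0} gives
        S = (1/4)(0.5 + 1 + 1) = 0.625."""
        s = FamilySample(
            "1", list("abcd"), np.array([1, 2, 2, 2]), 2,
            kin2=np.eye(4), x2=np.array([1.0, 0.5, 0.0, 0.0]), pi2=np.eye(4),
        )
        spec = design.one_locus(K=2)
        assert scorecore.score_unweighted(s, spec, "b1") == pytest.approx(0.625)

    def test_constant_column_scores_zero(self, rng):
        s = random_family(rng, K=2)
        s.x2 = np.full(s.n, 0.5)
        spec = design.one_locus(K=2)
        assert scorecore.score_unweighted(s, spec, "b1") == 0.0

    def test_score_is_linear_in_weights(self, rng):
        s = random_family(rng, K=4)
        spec = design.one_locus(K=4)
        C = scorecore.pair_weights(s, "equal")
        S1 = scorecore.family_scores(s, spec, spec.labels, C)
        S2 = scorecore.family_scores(s, spec, spec.labels, 2 * C)
        np.testing.assert_allclose(S2, 2 * S1, atol=1e-14)

    def test_three_member_hand_weighted_sum(self):
        s = FamilySample(
            "1", list("abc"), np.array([1, 2, 2]), 2,
            kin2=np.eye(3), x2=np.array([1.0, 0.5, 0.0]), pi2=np.eye(3),
        )
        C = np.full((3, 3), 0.0)
        C[0, 1], C[0, 2] = 2.0, 3.0
        spec = design.one_locus(K=2)
        got = scorecore.family_scores(s, spec, ("b1",), C)[0]
        assert got == pytest.approx(2.0 * 0.5 + 3.0 * 1.0)

    def test_non_informative_family_contributes_exact_zero(self, rng):
        s = random_family(rng, K=4)
        s.y[:] = 4
        spec = design.one_locus(K=4)
        C = scorecore.pair_weights(s, "equal")
        assert not s.informative
        assert (scorecore.family_scores(s, spec, spec.labels, C) == 0).all()


class TestPairWeights:
    def test_zero_nuisance_reduces_both_weightings_to_equal(self, rng):
        s = random_family(rng, K=4)
        fit = stub_fit(4, np.zeros(3))
        for mode in ("eq6", "eq7"):
            np.testing.assert_allclose(
                scorecore.pair_weights(s, mode, fit), 1.0 / s.n, atol=1e-14
            )

    def test_logistic_weight_hand_value(self):
        """x difference 1 and slope difference log 2 give u = log 2, so the
        first weight expression yields C = 2/(3n)."""
        s = two_member_sample()
        fit = stub_fit(2, np.array([np.log(2.0)]))
        C6 = scorecore.pair_weights(s, "eq6", fit)
        assert C6[0, 1] == pytest.approx(2.0 / (3.0 * 2))
        C7 = scorecore.pair_weights(s, "eq7", fit)
        assert C7[0, 1] == pytest.approx(8.0 * 2.0 / (2 * 27.0))

    def test_equal_weighted_score_recovers_unweighted(self, rng):
        spec = design.one_locus(K=4)
        for _ in range(5):
            s = random_family(rng, K=4)
            C = scorecore.pair_weights(s, "equal")
            Sw = scorecore.family_scores(s, spec, spec.labels, C)
            Su = [scorecore.score_unweighted(s, spec, lab) for lab in spec.labels]
            np.testing.assert_allclose(Sw, Su, atol=1e-14)


class TestVariance:
    def test_two_unrelated_members_main_effect(self):
        """Equal weights C = 1/2: Var-kernel = (1 + 1 - 0 - 0)/4 so the
        variance is sigma^2/2."""
        s = two_member_sample()
        spec = design.one_locus(K=2)
        C = scorecore.pair_weights(s, "equal")
        kern = scorecore.family_cov_model(s, spec, "b1", "b1", C)
        assert kern == pytest.approx(0.5)

    def test_clonal_family_has_zero_variance(self):
        s = two_member_sample(unrelated=False)
        spec = design.one_locus(K=2)
        C = scorecore.pair_weights(s, "equal")
        assert scorecore.family_cov_model(s, spec, "b1", "b1", C) == pytest.approx(0.0)

    def test_two_unrelated_members_product_term(self):
        s = two_member_sample()
        spec = design.dichotomous_two_locus()
        C = scorecore.pair_weights(s, "equal")
        kern = scorecore.family_cov_model(s, spec, "eta3", "eta3", C)
        assert kern == pytest.approx(0.5)   # (1*1 + 1*1)/4

    def test_product_clonal_zero(self):
        s = two_member_sample(unrelated=False)
        spec = design.dichotomous_two_locus()
        C = scorecore.pair_weights(s, "equal")
        assert scorecore.family_cov_model(s, spec, "eta3", "eta3", C) == pytest.approx(0.0)

    def test_fast_path_equals_quadruple_sum_oracle(self, rng):
        spec = design.full_two_locus()
        free = design.one_locus(K=4, var="x1", prefix="a")
        fams = [random_family(rng, K=4, with_x1=True, max_n=7) for _ in range(12)]
        fit = nuisance.fit_alpha(fams, free)
        pairs = [("b32", "b32"), ("b33", "b33"), ("b32", "b33"), ("b12", "b33")]
        for s in fams[:6]:
            C = scorecore.pair_weights(s, "eq6", fit)
            for g, h in pairs:
                R = scorecore._pair_kernel(s, spec, g, h, "assoc")
                want = weighted_cov_oracle(
                    s, None, spec.categories(g), None, spec.categories(h), C, R
                )
                got = scorecore.family_cov_model(s, spec, g, h, C, "assoc", "fast")
                naive = scorecore.family_cov_model(s, spec, g, h, C, "assoc", "naive")
                assert got == pytest.approx(want, abs=1e-10)
                assert naive == pytest.approx(want, abs=1e-12)

    def test_unlinked_main_terms_have_zero_model_covariance(self, rng):
        s = random_family(rng, K=4, with_x1=True)
        spec = design.full_two_locus()
        C = scorecore.pair_weights(s, "equal")
        # b11 is a locus-1 main term, b12 a locus-2 main term
        assert scorecore.family_cov_model(s, spec, "b11", "b12", C) == 0.0

    def test_empirical_diagonal_tracks_model_variance_under_null(self):
        """On ~1000 simulated null families the empirical and model-based
        variance of a single-category score agree within 15%."""
        coef0 = np.array([[-1.5, 0, 0, 0], [-2.5, 0, 0, 0], [-2.5, 0, 0, 0]])
        sim = simulator.simulate_sample(
            simulator.Scenario(coef=coef0), 1000,
            np.random.default_rng(7), apply_ascertainment=False,
        )
        fams = simulator.to_family_samples(sim, tested="causal")
        spec = design.one_locus(K=4)
        res_m = scorecore.score_test(fams, spec, ("b3",), kernel="model")
        res_e = scorecore.score_test(fams, spec, ("b3",), kernel="empirical")
        assert res_e.V[0, 0] == pytest.approx(res_m.V[0, 0], rel=0.15)

    def test_inconsistent_relatedness_raises(self):
        s = two_member_sample()
        s.pi2 = -np.eye(2)          # impossible sharing
        spec = design.one_locus(K=2)
        with pytest.raises(ValueError, match="negative model-based variance"):
            scorecore.model_covariance([s], spec, ("b1",), [scorecore.pair_weights(s, "equal")])


class TestStatistics:
    def test_zero_score_gives_unit_pvalue(self):
        T, df, p, bad = scorecore.test_joint(np.zeros(3), np.eye(3))
        assert T == 0.0 and p == 1.0 and not bad

    def test_scalar_chi_square_is_squared_z(self):
        S, v = 0.7, 0.2
        T, df, p, _ = scorecore.test_joint([S], [[v]])
        z, pz = scorecore.test_single(S, v)
        assert T == pytest.approx(z**2)
        assert p == pytest.approx(pz)
        assert df == 1

    def test_joint_statistic_invariant_to_reparameterization(self, rng):
        S = rng.normal(size=4)
        A0 = rng.normal(size=(4, 4))
        V = A0 @ A0.T + 0.5 * np.eye(4)
        B = rng.normal(size=(4, 4)) + np.eye(4)
        T1, df1, _, _ = scorecore.test_joint(S, V)
        T2, df2, _, _ = scorecore.test_joint(B @ S, B @ V @ B.T)
        assert T2 == pytest.approx(T1, rel=1e-8)
        assert df1 == df2 == 4

    def test_singular_covariance_uses_rank_for_df(self):
        V = np.ones((2, 2))
        T, df, p, bad = scorecore.test_joint(np.array([1.0, 1.0]), V)
        assert df == 1 and not bad
        # rank-1 pseudo-inverse: T = (S . q)^2 / lambda = 2 / 2
        assert T == pytest.approx(1.0)

    def test_all_zero_covariance_flagged_untestable(self):
        T, df, p, bad = scorecore.test_joint(np.array([0.5]), np.array([[0.0]]))
        assert bad and np.isnan(p)

    def test_category_swap_flips_z_sign(self, rng):
        s = random_family(rng, K=2)
        spec = design.one_locus(K=2)
        res = scorecore.score_test([s], spec, ("b1",), kernel="model")
        flipped = FamilySample(
            s.fam, list(reversed(s.ids)), np.sort(3 - s.y), 2,
            kin2=s.kin2[::-1, ::-1], x2=s.x2[::-1], pi2=s.pi2[::-1, ::-1],
        )
        res2 = scorecore.score_test([flipped], spec, ("b1",), kernel="model")
        assert res2.S[0] == pytest.approx(-res.S[0], abs=1e-12)
        if np.isfinite(res.z[0]):
            assert res2.z[0] == pytest.approx(-res.z[0], rel=1e-10)

    def test_adding_non_informative_family_changes_nothing(self, rng):
        fams = [random_family(rng, K=4) for _ in range(20)]
        extra = random_family(rng, K=4)
        extra.y[:] = 4
        spec = design.one_locus(K=4)
        a = scorecore.score_test(fams, spec, spec.labels, kernel="empirical")
        b = scorecore.score_test(fams + [extra], spec, spec.labels, kernel="empirical")
        np.testing.assert_allclose(a.S, b.S, atol=1e-14)
        assert a.p == pytest.approx(b.p, abs=1e-12)
        assert b.n_informative == a.n_informative + (1 if extra.informative else 0)
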