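import itertools
import math

import numpy as np
import pytest
from scipy import stats

from concur.assoc import (
    PhenotypeTable,
    concur_test,
    fit_null,
    holm_adjust,
    null_weights,
    permutation_negative_control,
    pvalue_weighted_chisq,
    score_statistic,
)
from concur.cnv_io import CNVDataset, CNVRecord, DosageMode
from concur.curves import DosageTransform
from concur.kernel import KernelMatrix, cauc_matrix
from concur._perm_moments import permutation_quadform_moments

from conftest import random_small_dataset


def phen(y, kind="continuous", X=None, ids=None):
    n = len(y)
    ids = ids or [f"S{i}" for i in range(n)]
    return PhenotypeTable(ids, np.asarray(y, float), kind, X)


class TestFitNull:
    def test_intercept_only_continuous_is_mean_and_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.5, 50)
        fit = fit_null(phen(y))
        assert fit.coefficients[0] == pytest.approx(y.mean())
        assert fit.residual_variance == pytest.approx(y.var(ddof=1))

    def test_intercept_only_binary_is_logit_prevalence(self):
        y = np.array([1.0] * 10 + [0.0] * 30)
        fit = fit_null(phen(y, "binary"))
        assert fit.coefficients[0] == pytest.approx(math.log(0.25 / 0.75))
        np.testing.assert_allclose(fit.fitted_means, 0.25)

    def test_logistic_slope_recovered_at_large_n(self):
        rng = np.random.default_rng(1)
        n = 50_000
        X = rng.binomial(1, 0.5, n).astype(float)
        eta = -2.0 + math.log(1.1) * X
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_null(phen(y, "binary", X))
        assert fit.coefficients[1] == pytest.approx(math.log(1.1), abs=0.05)

    def test_one_class_binary_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_null(phen(np.zeros(20), "binary"))

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_null(PhenotypeTable([f"S{i}" for i in range(30)],
                                    rng.normal(size=30), "continuous", X,
                                    ["a", "b"]))


class TestScoreStatistic:
    def test_zero_residuals_give_zero(self):
        from concur.assoc import NullModelFit

        y = np.arange(10.0)
        fit = NullModelFit(
            "continuous", np.array([0.0]), fitted_means=y,
            design=np.ones((10, 1)), trait=y, residual_variance=1.0,
        )
        K = KernelMatrix(np.eye(10), [f"S{i}" for i in range(10)])
        assert score_statistic(fit, K) == 0.0

    def test_degenerate_constant_trait_rejected_in_fit(self):
        with pytest.raises(ValueError, match="zero residual variance"):
            fit_null(phen(np.full(10, 3.0)))

    def test_identity_kernel_intercept_only_identity_value(self):
        rng = np.random.default_rng(3)
        n = 37
        y = rng.normal(size=n)
        fit = fit_null(phen(y))
        K = KernelMatrix(np.eye(n), [f"S{i}" for i in range(n)])
        # r'r / (2 sigma2) with sigma2 = r'r/(n-1) is (n-1)/2 exactly
        assert score_statistic(fit, K) == pytest.approx((n - 1) / 2)

    def test_binary_quadratic_form_by_hand(self):
        y = np.array([1.0, 0.0, 0.0, 1.0])
        fit = fit_null(phen(y, "binary"))
        K = KernelMatrix(
            np.array(
                [
                    [4.0, 2.0, 0.0, 1.0],
                    [2.0, 3.0, 1.0, 0.0],
                    [0.0, 1.0, 2.0, 0.0],
                    [1.0, 0.0, 0.0, 5.0],
                ]
            ),
            [f"S{i}" for i in range(4)],
        )
        r = y - 0.5
        assert score_statistic(fit, K) == pytest.approx(0.5 * r @ K.values @ r)


class TestNullWeights:
    def test_projection_kernel_gives_half_weights(self):
        rng = np.random.default_rng(4)
        n, r = 30, 2
        X = rng.normal(size=(n, r))
        y = rng.normal(size=n)
        fit = fit_null(phen(y, "continuous", X))
        Xd = np.column_stack([np.ones(n), X])
        P0 = np.eye(n) - Xd @ np.linalg.solve(Xd.T @ Xd, Xd.T)
        lam = null_weights(fit, KernelMatrix(P0, [f"S{i}" for i in range(n)]))
        assert lam.size == n - r - 1
        np.testing.assert_allclose(lam, 0.5, atol=1e-10)

    def test_zero_kernel_gives_empty_weights(self):
        y = np.random.default_rng(5).normal(size=12)
        fit = fit_null(phen(y))
        lam = null_weights(fit, KernelMatrix(np.zeros((12, 12)), [f"S{i}" for i in range(12)]))
        assert lam.size == 0

    def test_weighted_chisq_tail_matches_gaussian_parametric_draws(self):
        # the projection eigenvalues describe T under Gaussian residuals:
        # compare the davies tail with a large parametric simulation
        rng = np.random.default_rng(6)
        ds = random_small_dataset(rng, n_samples=30, max_records=6)
        K = cauc_matrix(ds, DosageTransform.from_mode(ds.mode))
        y = rng.normal(size=30)
        fit = fit_null(phen(y, ids=list(ds.roster)))
        lam = null_weights(fit, K)
        q = 1.5 * lam.sum()
        p_analytic, _ = pvalue_weighted_chisq(q, lam)
        B = 200_000
        draws = rng.chisquare(1, (B, lam.size)) @ lam
        mc = np.mean(draws > q)
        se = math.sqrt(mc * (1 - mc) / B)
        assert abs(p_analytic - mc) <= 3 * se

    def test_conditional_pvalue_matches_permutation_continuous(self):
        rng = np.random.default_rng(6)
        ds = random_small_dataset(rng, n_samples=30, max_records=6)
        K = cauc_matrix(ds, DosageTransform.from_mode(ds.mode))
        y = rng.normal(size=30)
        res = concur_test(ds, phen(y, ids=list(ds.roster)))
        fit = fit_null(phen(y, ids=list(ds.roster)))
        B = 50_000
        r = fit.residuals
        perms = np.array([rng.permutation(r) for _ in range(B)])
        Ts = np.einsum("bi,ij,bj->b", perms, K.values, perms) / (
            2 * fit.residual_variance
        )
        p_perm = (1 + np.sum(Ts >= res.statistic)) / (B + 1)
        se = math.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p_value - p_perm) <= 3 * se


class TestPvalueWeightedChisq:
    @pytest.mark.parametrize(
        "q,weights,expected",
        [
            (3.841459, [1.0], 0.05),               # chi2_1 upper 5% point
            (7.814728, [1.0, 1.0, 1.0], 0.05),     # chi2_3 upper 5% point
            (0.0, [2.0, 1.0], 1.0),
        ],
    )
    def test_chi_square_closed_forms(self, q, weights, expected):
        p, method = pvalue_weighted_chisq(q, np.array(weights))
        assert p == pytest.approx(expected, abs=1e-6)
        assert method == "davies"

    def test_matches_chi2_sf_over_grid(self):
        for df in (1, 2, 5, 20):
            for q in (0.1, 1.0, 5.0, 20.0, 40.0):
                p, _ = pvalue_weighted_chisq(q, np.ones(df))
                assert p == pytest.approx(stats.chi2.sf(q, df), abs=1e-8)

    def test_unequal_weights_match_monte_carlo(self):
        rng = np.random.default_rng(7)
        lam = np.array([5.0, 2.0, 1.0, 0.3, 0.01])
        draws = rng.chisquare(1, (400_000, lam.size)) @ lam
        q = 15.0
        p, _ = pvalue_weighted_chisq(q, lam)
        mc = np.mean(draws > q)
        assert p == pytest.approx(mc, abs=4 * math.sqrt(mc * (1 - mc) / 400_000))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            pvalue_weighted_chisq(-1.0, np.array([1.0]))


class TestPermutationMoments:
    def test_exact_against_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(4):
            n = int(rng.integers(7, 9))
            M = rng.normal(size=(n, n))
            A = M @ M.T
            r = rng.normal(size=n)
            qs = np.array(
                [r[list(p)] @ A @ r[list(p)] for p in itertools.permutations(range(n))]
            )
            mu, var, mu3 = permutation_quadform_moments(A, r)
            assert mu == pytest.approx(qs.mean())
            assert var == pytest.approx(qs.var())
            assert mu3 == pytest.approx(np.mean((qs - qs.mean()) ** 3))

    def test_binary_small_sample_pvalue_matches_permutation(self):
        # the conditional moment-matched p-value vs a large permutation draw
        from concur.simulate import TGPParams, generate_tgp_like

        rng = np.random.default_rng(9)
        ds = generate_tgp_like(
            40,
            TGPParams(n_loci=30, freq_range=(0.05, 0.25), max_locus_freq=0.5,
                      chroms=(1, 2)),
            rng,
        )
        K = cauc_matrix(ds, DosageTransform.from_mode(ds.mode))
        y = np.array([1.0] * 15 + [0.0] * 25)
        res = concur_test(ds, phen(y, "binary", ids=list(ds.roster)))
        assert res.method == "moment"
        B = 50_000
        r0 = y - y.mean()
        perms = np.array([rng.permutation(r0) for _ in range(B)])
        Ts = 0.5 * np.einsum("bi,ij,bj->b", perms, K.values, perms)
        p_perm = (1 + np.sum(Ts >= res.statistic)) / (B + 1)
        se = math.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p_value - p_perm) <= 3 * se


class TestConcurTest:
    def test_zero_kernel_gives_p_one(self):
        ds = CNVDataset([], [f"S{i}" for i in range(20)])
        y = np.random.default_rng(10).normal(size=20)
        res = concur_test(ds, phen(y, ids=list(ds.roster)))
        assert res.p_value == 1.0 and res.degenerate

    def test_shift_invariance_continuous(self):
        rng = np.random.default_rng(11)
        ds = random_small_dataset(rng, n_samples=25, max_records=4)
        y = rng.normal(size=25)
        r1 = concur_test(ds, phen(y, ids=list(ds.roster)))
        r2 = concur_test(ds, phen(y + 100.0, ids=list(ds.roster)))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_consistent_relabeling_invariance(self):
        rng = np.random.default_rng(12)
        ds = random_small_dataset(rng, n_samples=15, max_records=4)
        y = rng.normal(size=15)
        r1 = concur_test(ds, phen(y, ids=list(ds.roster)))
        perm = rng.permutation(15)
        ids2 = [ds.roster[i] for i in perm]
        ds2 = ds.subset_samples(ids2)
        r2 = concur_test(ds2, phen(y[perm], ids=ids2))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_unmatched_samples_dropped(self):
        rng = np.random.default_rng(13)
        ds = random_small_dataset(rng, n_samples=10, max_records=3)
        y = rng.normal(size=8)
        res = concur_test(ds, phen(y, ids=list(ds.roster[:8])))
        assert res.n == 8

    def test_no_shared_samples_is_an_error(self):
        ds = CNVDataset([], ["A", "B"])
        with pytest.raises(ValueError, match="no samples shared"):
            concur_test(ds, phen(np.zeros(2), ids=["X", "Y"]))


class TestHolm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([0.9, 0.9], [1.0, 1.0]),
        ],
    )
    def test_hand_executed_examples(self, raw, expected):
        np.testing.assert_allclose(holm_adjust(raw), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestPermutationNegativeControl:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        ds = random_small_dataset(rng, n_samples=20, max_records=4)
        y = rng.binomial(1, 0.5, 20).astype(float)
        p1 = permutation_negative_control(ds, phen(y, "binary", ids=list(ds.roster)), B=3, seed=7)
        p2 = permutation_negative_control(ds, phen(y, "binary", ids=list(ds.roster)), B=3, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_trait_surfaces_clean_error(self):
        rng = np.random.default_rng(15)
        ds = random_small_dataset(rng, n_samples=12, max_records=3)
        with pytest.raises(ValueError, match="single class"):
            permutation_negative_control(
                ds, phen(np.ones(12), "binary", ids=list(ds.roster)), B=1, seed=0
            )
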