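import numpy as np
import pytest
from scipy.stats import chi2_contingency, norm

import odsreg as o


class TestSolveProbitThresholds:
    def test_median_target_both_methods(self):
        # the covariate mixture -X1 + 0.5 X2 is symmetric about -0.25, so a
        # cumulative target of 0.5 gives a threshold of 0.25 either way
        for method in ("mean", "marginal"):
            a = o.solve_probit_thresholds(np.array([0.5, 0.5]), method=method)
            np.testing.assert_allclose(a, [0.25], atol=1e-10)

    def test_mean_method_closed_form(self):
        props = np.array([0.3, 0.35, 0.35])
        a = o.solve_probit_thresholds(props, method="mean")
        np.testing.assert_allclose(a, norm.ppf([0.3, 0.65]) + 0.25, rtol=1e-12)

    def test_marginal_method_monte_carlo_oracle(self):
        props = np.array([0.3, 0.35, 0.35])  # K=3 second scenario variant
        a = o.solve_probit_thresholds(props, method="marginal")
        rng = np.random.default_rng(77)
        M = 2_000_000
        x1 = rng.random(M)
        x2 = rng.integers(0, 2, M)
        for k, target in enumerate([0.3, 0.65]):
            mc = norm.cdf(a[k] - x1 + 0.5 * x2).mean()
            se = np.sqrt(target * (1 - target) / M)
            assert abs(mc - target) < 4 * se + 1e-4

    def test_increasing(self):
        a = o.solve_probit_thresholds(
            np.array([0.04, 0.24, 0.24, 0.24, 0.24]), method="marginal"
        )
        assert np.all(np.diff(a) > 0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            o.solve_probit_thresholds(np.array([1.0]))
        with pytest.raises(ValueError):
            o.solve_probit_thresholds(np.array([0.5, -0.1, 0.6]))


class TestScenarios:
    def test_table_lookup(self):
        s = o.get_scenario("L5", 5)
        np.testing.assert_allclose(
            s.proportions, [0.8, 0.05, 0.05, 0.05, 0.05]
        )
        assert s.n_k == 80 and s.N == 10_000
        s3 = o.get_scenario("m3", 3)
        np.testing.assert_allclose(s3.proportions, [0.25, 0.5, 0.25])
        assert s3.n_k == 100

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            o.get_scenario("Z9", 5)

    def test_mean_method_weight_cv_matches_published_table(self):
        # realized proportions under mean-calibrated thresholds give the
        # published mean weight CVs (e.g. 1.46 for L(v) K=5, 1.17 K=3)
        def mixture_cdf(a):
            # independent closed form: E Phi(a - U(0,1) + 0.5 Bern(0.5))
            G = lambda x: x * norm.cdf(x) + norm.pdf(x)
            return 0.5 * (G(a) - G(a - 1.0)) + 0.5 * (G(a + 0.5) - G(a - 0.5))

        for label, K, expected in [
            ("L5", 5, 1.46),
            ("L3", 5, 0.52),
            ("M3", 5, 0.44),
            ("L5", 3, 1.17),
            ("L1", 5, 0.38),
        ]:
            scen = o.get_scenario(label, K)
            cum = mixture_cdf(scen.alpha_star)
            props = np.diff(np.concatenate([[0.0], cum, [1.0]]))
            w = props * scen.N / scen.n_k
            counts = np.full(K, scen.n_k)
            mean = np.average(w, weights=counts)
            sd = np.sqrt(np.average((w - mean) ** 2, weights=counts))
            assert round(sd / mean, 2) == expected


class TestGenerateProbitCohort:
    def test_marginal_shares_match_targets(self):
        scen = o.get_scenario("L2", 5, threshold_method="marginal")
        M = 200_000
        cohort = o.generate_probit_cohort(scen, M, seed=5)
        shares = np.bincount(cohort.y)[1:] / M
        se = np.sqrt(0.2 * 0.8 / M)
        np.testing.assert_allclose(shares, 0.2, atol=4 * se)

    def test_seeded_reproducibility(self):
        scen = o.get_scenario("M3", 3)
        c1 = o.generate_probit_cohort(scen, 5_000, seed=9)
        c2 = o.generate_probit_cohort(scen, 5_000, seed=9)
        np.testing.assert_array_equal(c1.y, c2.y)
        np.testing.assert_array_equal(c1.X, c2.X)

    def test_zero_size_raises(self):
        with pytest.raises(ValueError):
            o.generate_probit_cohort(o.get_scenario("L1", 3), 0, seed=1)


class TestGenerateModelCohort:
    def test_shares_match_implied_marginals(self, rng):
        fam = o.ModelFamily("cm", 3, 2)
        truth = o.Parameters(np.array([-0.8, 0.6]), np.array([-1.0, 0.5]))
        N = 100_000
        cohort = o.generate_model_cohort(fam, truth, N, seed=3)
        X = cohort.X
        implied = o.category_probs(fam, truth, X).mean(axis=0)
        shares = np.bincount(cohort.y)[1:] / N
        se = np.sqrt(implied * (1 - implied) / N)
        np.testing.assert_array_less(np.abs(shares - implied), 4 * se)

    def test_null_slope_gives_independence(self):
        fam = o.ModelFamily("ac", 3, 2)
        truth = o.Parameters(np.array([0.2, -0.1]), np.zeros(2))
        rejected = 0
        for seed in range(30):
            cohort = o.generate_model_cohort(fam, truth, 4_000, seed=seed)
            table = np.array(
                [
                    np.bincount(cohort.y[cohort.X[:, 1] == v], minlength=4)[1:]
                    for v in (0.0, 1.0)
                ]
            )
            # X2 is continuous here; bin it instead
            x = cohort.X[:, 0]
            table = np.array(
                [
                    np.bincount(cohort.y[x <= np.median(x)], minlength=4)[1:],
                    np.bincount(cohort.y[x > np.median(x)], minlength=4)[1:],
                ]
            )
            if chi2_contingency(table)[1] < 0.001:
                rejected += 1
        assert rejected <= 1

    def test_seeded_reproducibility(self):
        fam = o.ModelFamily("cr", 3, 2)
        truth = o.Parameters(np.array([-0.5, 0.0]), np.array([0.4, -0.2]))
        c1 = o.generate_model_cohort(fam, truth, 2_000, seed=17)
        c2 = o.generate_model_cohort(fam, truth, 2_000, seed=17)
        np.testing.assert_array_equal(c1.y, c2.y)

    def test_zero_size_raises(self):
        fam = o.ModelFamily("cm", 2, 1)
        with pytest.raises(ValueError):
            o.generate_model_cohort(
                fam, o.Parameters(np.zeros(1), np.zeros(1)), 0, seed=1
            )


class TestMetrics:
    def test_relative_bias_trivia(self):
        assert o.relative_bias(np.array([2.0, 2.0]), 2.0) == 0.0
        np.testing.assert_allclose(
            o.relative_bias(np.array([1.1, 1.1, 1.1]), 1.0), 10.0
        )

    def test_relative_bias_hand_instance(self):
        est = np.array([1.2, 0.9, 1.5])
        truth = 1.5
        expected = ((1.2 / 1.5 - 1) + (0.9 / 1.5 - 1) + (1.5 / 1.5 - 1)) / 3 * 100
        np.testing.assert_allclose(o.relative_bias(est, truth), expected)

    def test_relative_error_se_trivia(self):
        est = np.array([1.0, 2.0, 3.0, 4.0])
        ese = est.std(ddof=1)
        np.testing.assert_allclose(
            o.relative_error_se(np.full(4, ese), est), 0.0, atol=1e-12
        )
        np.testing.assert_allclose(
            o.relative_error_se(np.full(4, 2 * ese), est), 100.0, atol=1e-12
        )

    def test_relative_error_se_hand_instance(self):
        est = np.array([0.8, 1.2, 1.1, 0.9])
        se = np.array([0.2, 0.25, 0.15, 0.2])
        expected = (se.mean() / est.std(ddof=1) - 1) * 100
        np.testing.assert_allclose(o.relative_error_se(se, est), expected)

    def test_rrmse_trivia_and_hand(self):
        a = np.array([1.0, 2.0, 3.0])
        assert o.rrmse(a, a, 1.5) == 1.0
        assert o.rrmse(np.full(3, 2.0), a, 2.0) == 0.0
        w = np.array([1.1, 0.9, 1.2])
        u = np.array([1.3, 0.8, 1.4])
        expected = np.sqrt(np.mean((w - 1.0) ** 2) / np.mean((u - 1.0) ** 2))
        np.testing.assert_allclose(o.rrmse(w, u, 1.0), expected)


class TestRunStudy:
    @pytest.fixture
    def small_truth(self):
        return o.Parameters(np.array([-1.5, -0.2, 0.9]), np.array([-1.2, 0.6]))

    def test_single_replicate_rb(self, small_truth):
        scen = o.Scenario("L2", 4, np.full(4, 0.25), N=4_000, n_k=60)
        res = o.run_study(scen, "cm", R=1, seed=5, truth=small_truth)
        s = res.summary()
        j = res.names.index("beta1")
        np.testing.assert_allclose(
            s.loc[s.parameter == "beta1", "RB_u"].item(),
            (res.estimates_u[0, j] / res.truth[j] - 1) * 100,
        )

    def test_same_seed_identical(self, small_truth):
        scen = o.Scenario("L2", 4, np.full(4, 0.25), N=3_000, n_k=50)
        r1 = o.run_study(scen, "cm", R=3, seed=8, truth=small_truth)
        r2 = o.run_study(scen, "cm", R=3, seed=8, truth=small_truth)
        np.testing.assert_array_equal(r1.estimates_w, r2.estimates_w)
        np.testing.assert_array_equal(r1.se_w, r2.se_w)

    def test_replicate_table_shape(self, small_truth):
        scen = o.Scenario("L2", 4, np.full(4, 0.25), N=3_000, n_k=50)
        res = o.run_study(scen, "cm", R=4, seed=8, truth=small_truth)
        reps = res.replicates()
        assert len(reps) == 4 * len(res.names)
        assert res.n_failed == 0

    def test_proportional_allocation_null(self, small_truth):
        # n_k proportional to realized N_k makes weights constant, so the
        # weighted fit equals the unweighted fit and RRMSE is ~1
        fam = o.ModelFamily("cm", 4, 2)
        cohort = o.generate_model_cohort(fam, small_truth, 20_000, seed=3)
        N_k = np.bincount(cohort.y)[1:]
        n_k = (N_k * 0.1).astype(int)
        f = n_k / N_k
        assert np.allclose(f, f[0], atol=2e-4)
        sample, _ = o.sample_ods(cohort, n_k, seed=4)
        fu = o.fit(fam, o.SampleData(sample.y, sample.X))
        fw = o.fit(fam, sample)
        np.testing.assert_allclose(fw.theta, fu.theta, atol=5e-3)

    def test_proportional_allocation_rrmse_near_one(self):
        scen = o.get_scenario("L2", 5, N=6_000)  # equal shares
        # truth with ~equal marginal category shares: alpha = logit(cum) - beta'E[X]
        beta = np.array([-1.5, 0.7])
        cum = np.array([0.2, 0.4, 0.6, 0.8])
        alpha = np.log(cum / (1 - cum)) - beta @ np.array([0.5, 0.5])
        truth = o.Parameters(alpha, beta)
        res = o.run_study(scen, "cm", R=150, seed=12, truth=truth, n_k=80)
        s = res.summary().set_index("parameter")
        for b in ("beta1", "beta2"):
            assert abs(s.loc[b, "RRMSE"] - 1.0) < 0.1


class TestCalibrateTruth:
    def test_smoke_and_constraints(self):
        scen = o.get_scenario("L2", 3)
        truth = o.calibrate_truth(scen, ("sm", "cm"), M=20_000, seed=2)
        sm = truth.params["sm"]
        assert sm.phi[0] == 1.0 and sm.phi[-1] == 0.0
        cm = truth.params["cm"]
        assert np.all(np.diff(cm.alpha) > 0)
        assert truth.M == 20_000
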