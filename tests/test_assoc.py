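"""Tests for the logistic association tests and method dispatch."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

import robustps as rps
from robustps.assoc import CHI2_1_MEDIAN, _fit_logit


def expand_table(case_counts, control_counts):
    """Genotype/phenotype vectors from 0/1/2 counts in cases and controls."""
    g, y = [], []
    for dose, (nca, nco) in enumerate(zip(case_counts, control_counts)):
        g += [dose] * (nca + nco)
        y += [1] * nca + [0] * nco
    return np.asarray(g, dtype=float), np.asarray(y, dtype=float)


class TestTrendTest:
    def test_balanced_identical_distributions_null(self):
        g, y = expand_table((10, 20, 10), (10, 20, 10))
        res = rps.trend_test(g, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_constant_genotype_degenerate(self):
        y = np.array([0, 1] * 20)
        res = rps.trend_test(np.ones(40), y)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.status == "degenerate"

    def test_matches_direct_likelihood_maximisation(self):
        # cases (10,20,10), controls (20,20,0): maximise the binomial
        # log-likelihood over (b0, b1) directly as an independent oracle
        g, y = expand_table((10, 20, 10), (20, 20, 0))

        def nll(params):
            eta = params[0] + params[1] * g
            return -(y * eta - np.logaddexp(0.0, eta)).sum()

        opt = optimize.minimize(nll, [0.0, 0.0], method="BFGS")
        n1, n0 = y.sum(), (1 - y).sum()
        ll0 = n1 * np.log(n1 / y.size) + n0 * np.log(n0 / y.size)
        expected_stat = 2.0 * (-opt.fun - ll0)
        res = rps.trend_test(g, y)
        assert res.statistic == pytest.approx(expected_stat, abs=1e-6)
        assert res.beta_hat == pytest.approx(opt.x[1], abs=1e-5)

    def test_single_class_phenotype_rejected(self):
        with pytest.raises(ValueError):
            rps.trend_test(np.array([0.0, 1.0]), np.array([1, 1]))


class TestIRLSAgainstStatsmodels:
    def test_coefficients_and_likelihood_match(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        x = rng.normal(size=(n, 2))
        eta = -0.2 + 0.4 * g + 0.3 * x[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        exog = np.column_stack([np.ones(n), g, x])
        ours = _fit_logit(y, exog)
        ref = sm.Logit(y, exog).fit(disp=0)
        assert np.allclose(ours.params, ref.params, atol=1e-8)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-8)
        assert np.allclose(ours.bse, ref.bse, rtol=1e-6)

    def test_separated_fit_finite_deviance(self):
        # quasi-complete separation: statsmodels' Newton solver fails here
        # while the IRLS path converges in deviance and flags separation
        g = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        exog = np.column_stack([np.ones(40), g])
        ours = _fit_logit(y, exog)
        assert ours.separated
        assert np.isfinite(ours.llf)
        assert ours.llf == pytest.approx(0.0, abs=1e-4)


class TestAdjustedTest:
    def test_reduces_to_trend_without_covariates(self, rng):
        g = rng.binomial(2, 0.4, 300).astype(float)
        y = rng.integers(0, 2, 300)
        a = rps.trend_test(g, y)
        b = rps.adjusted_test(g, y)
        assert abs(a.p_value - b.p_value) < 1e-10
        assert abs(a.statistic - b.statistic) < 1e-10

    def test_confounded_signal_removed_by_covariate(self):
        # genotype depends on a latent confounder that also drives disease;
        # adjusting for the confounder should restore the nominal rate
        gen = np.random.default_rng(14)
        n = 800
        n_unadj, n_adj, reps = 0, 0, 200
        for _ in range(reps):
            u = gen.normal(size=n)
            freq = 1 / (1 + np.exp(-u))
            g = gen.binomial(2, 0.2 + 0.6 * freq).astype(float)
            y = (gen.random(n) < 1 / (1 + np.exp(-1.5 * u))).astype(int)
            n_unadj += rps.trend_test(g, y).p_value < 0.01
            n_adj += rps.adjusted_test(g, y, pcs=u[:, None]).p_value < 0.01
        assert n_unadj / reps > 0.3
        se = np.sqrt(0.01 * 0.99 / reps)
        assert n_adj / reps < 0.01 + 4 * se

    def test_lrt_and_wald_agree_asymptotically(self, rng):
        g = rng.binomial(2, 0.5, 1000).astype(float)
        x = rng.normal(size=(1000, 1))
        eta = 0.25 * g - 0.3 * x[:, 0]
        y = (rng.random(1000) < 1 / (1 + np.exp(-eta))).astype(int)
        lrt = rps.adjusted_test(g, y, pcs=x, test="lrt")
        wald = rps.adjusted_test(g, y, pcs=x, test="wald")
        ratio = lrt.p_value / wald.p_value
        assert 0.5 < ratio < 2.0

    def test_collinear_cluster_dummies_dropped(self, rng):
        g = rng.binomial(2, 0.4, 200).astype(float)
        y = rng.integers(0, 2, 200)
        clusters = np.repeat([0, 1], 100)
        dup = np.column_stack([clusters, clusters]).astype(float)
        with pytest.warns(RuntimeWarning):
            res = rps.adjusted_test(g, y, pcs=dup)
        assert np.isfinite(res.p_value)


class TestGenomicControl:
    def test_null_calibrated_panel_leaves_results_unchanged(self):
        base = [
            rps.AssociationResult("s1", "trend", CHI2_1_MEDIAN, 1, 0.5, 0.0, 100)
        ]
        corrected, lam = rps.genomic_control(base, np.full(50, CHI2_1_MEDIAN))
        assert lam == pytest.approx(1.0)
        assert corrected[0].statistic == pytest.approx(CHI2_1_MEDIAN)

    def test_doubled_median_halves_statistics(self):
        base = [rps.AssociationResult("s1", "trend", 4.0, 1, 0.04, 0.1, 100)]
        corrected, lam = rps.genomic_control(base, np.full(11, 2 * CHI2_1_MEDIAN))
        assert lam == pytest.approx(2.0)
        assert corrected[0].statistic == pytest.approx(2.0)
        assert corrected[0].p_value == pytest.approx(float(stats.chi2.sf(2.0, 1)))

    def test_lambda_floor_at_one(self):
        base = [rps.AssociationResult("s1", "trend", 1.0, 1, 0.3, 0.1, 100)]
        corrected, lam = rps.genomic_control(base, np.full(20, 0.1))
        assert lam == 1.0
        assert corrected[0].statistic == 1.0

    def test_duplication_invariance(self, rng):
        base = [rps.AssociationResult("s1", "trend", 3.0, 1, 0.08, 0.1, 100)]
        panel = rng.chisquare(1, 101)
        _, lam1 = rps.genomic_control(base, panel)
        _, lam2 = rps.genomic_control(base, np.concatenate([panel, panel]))
        assert lam1 == pytest.approx(lam2)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            rps.genomic_control([], np.array([]))


class TestInflationFactor:
    def test_null_simulation_near_one(self):
        gen = np.random.default_rng(17)
        n = 1000
        stats_list = []
        y = np.repeat([0, 1], n // 2)
        for _ in range(2000):
            g = gen.binomial(2, 0.3, n).astype(float)
            stats_list.append(rps.trend_test(g, y).statistic)
        lam = rps.inflation_factor(stats_list)
        assert 0.9 < lam < 1.1

    def test_scale_equivariance(self, rng):
        s = rng.chisquare(1, 500)
        assert rps.inflation_factor(2 * s) == pytest.approx(2 * rps.inflation_factor(s))

    def test_stratified_inflation_above_one(self):
        gen = np.random.default_rng(23)
        ds = rps.simulate_discrete(
            rps.scenario("S2", n_inference_snps=400, n_testing_snps=0), gen
        )
        X = ds.inference
        y = ds.phenotype
        stats_list = [rps.trend_test(X[:, j], y).statistic for j in range(400)]
        assert rps.inflation_factor(stats_list) > 1.5


class TestMultiplicity:
    def test_single_p_unchanged(self):
        assert rps.adjust_multiplicity([0.37], "holm")[0] == pytest.approx(0.37)

    def test_holm_hand_example(self):
        out = rps.adjust_multiplicity([0.01, 0.02, 0.03], "holm")
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_bh_identical_ps(self):
        out = rps.adjust_multiplicity([0.2] * 7, "bh")
        assert np.allclose(out, 0.2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
        proc=st.sampled_from(["holm", "bh"]),
    )
    def test_matches_statsmodels(self, p, proc):
        ours = rps.adjust_multiplicity(p, proc)
        ref = multipletests(p, method={"holm": "holm", "bh": "fdr_bh"}[proc])[1]
        assert np.allclose(ours, ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rps.adjust_multiplicity([1.2], "bh")


class TestRunMethod:
    def test_unknown_method_rejected(self, s2_small, rng):
        with pytest.raises(ValueError):
            rps.run_method(s2_small, "eigencorrection", rng=rng)

    def test_mds_reduces_to_pca_with_one_cluster(self, rng):
        # one homogeneous population: Gap should find a single cluster and
        # the two methods' p-values coincide
        gen = np.random.default_rng(31)
        scen = rps.DiscreteScenario(
            n_pops=1,
            case_props=(1.0,),
            control_props=(1.0,),
            n_inference_snps=400,
            n_testing_snps=40,
        )
        ds = rps.simulate_discrete(scen, gen)
        res_pca, det_pca = rps.run_method(
            ds, "pca", rng=np.random.default_rng(0), gap_B=50, return_details=True
        )
        res_mds, det_mds = rps.run_method(
            ds, "mds", rng=np.random.default_rng(0), gap_B=50, return_details=True
        )
        assert det_mds.stratification.cluster_count == 1
        p1 = np.array([r.p_value for r in res_pca])
        p2 = np.array([r.p_value for r in res_mds])
        assert np.allclose(p1, p2, atol=1e-12)

    def test_gc_lambda_reported_and_statistics_scaled(self, s2_small):
        res_trend = rps.run_method(s2_small, "trend", rng=np.random.default_rng(0))
        res_gc, det = rps.run_method(
            s2_small, "gc", rng=np.random.default_rng(0), return_details=True
        )
        assert det.gc_lambda >= 1.0
        t = np.array([r.statistic for r in res_trend])
        c = np.array([r.statistic for r in res_gc])
        assert np.allclose(c, t / det.gc_lambda, atol=1e-10)

    def test_determinism_under_fixed_seed(self, s2_small):
        a = rps.run_method(s2_small, "mds", rng=np.random.default_rng(5), gap_B=30)
        b = rps.run_method(s2_small, "mds", rng=np.random.default_rng(5), gap_B=30)
        assert [r.p_value for r in a] == [r.p_value for r in b]

    def test_results_cover_all_testing_snps(self, s2_small):
        res = rps.run_method(s2_small, "trend", rng=np.random.default_rng(0))
        n_testing = int(np.isin(s2_small.snp_role, ("random", "differentiated", "causal")).sum())
        assert len(res) == n_testing
        assert all(0.0 <= r.p_value <= 1.0 for r in res)
        assert all(r.statistic >= 0 for r in res)
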