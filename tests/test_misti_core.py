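import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2, kstest

from gxescan import misti_core
from gxescan.expression import harmonize_alleles, predict_expression
from gxescan.misti_core import (
    ConvergenceError,
    RankDeficiencyError,
    combine_components,
    fit_null_logistic,
    fixed_effect_score_test,
    irls_logistic,
    mixture_chisq_pvalue,
    random_effect_score_test,
)
from gxescan.synthetic_data import SimScenario, simulate_cohort

from conftest import make_cohort
from test_expression import make_weight_set


class TestNullFit:
    def test_intercept_only_limit(self):
        """With the outcome independent of everything, fitted risks hug the
        case fraction: their mean matches it exactly (intercept score
        equation) and their spread is pure estimation noise."""
        rng = np.random.default_rng(0)
        y = (rng.random(400) < 0.3).astype(int)
        cohort = make_cohort(y)
        fit = fit_null_logistic(cohort, None, "diabetes")
        assert fit.mu.mean() == pytest.approx(y.mean(), abs=1e-8)
        assert np.std(fit.mu) < 0.08

    def test_matches_statsmodels_loglik(self, small_cohort):
        """IRLS solution agrees with an independent optimizer on 200 samples."""
        g, cohort, wss = small_cohort
        sub = cohort.subset(np.arange(cohort.n_samples) < 200)
        ws = harmonize_alleles(wss[0], g)
        xhat = predict_expression(ws, g.take_samples(list(range(200))))
        fit = fit_null_logistic(sub, xhat, "bmi", include_sex=True)
        ref = sm.Logit(fit.y, fit.X).fit(disp=False, method="newton")
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-5)

    def test_duplicated_covariate_column_raises(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        cohort = make_cohort(y)
        cohort.data["pc2"] = cohort.data["pc1"]  # exact duplicate
        with pytest.raises(RankDeficiencyError):
            fit_null_logistic(cohort, None, "bmi")

    def test_score_equations_satisfied_at_optimum(self, small_cohort):
        g, cohort, _ = small_cohort
        fit = fit_null_logistic(cohort, None, "bmi", include_sex=True)
        score = fit.X.T @ (fit.y - fit.mu)
        assert np.max(np.abs(score)) < 1e-6
        assert np.all((fit.mu > 0) & (fit.mu < 1))

    def test_separation_detected(self):
        y = np.repeat([0, 1], 50)
        cohort = make_cohort(y, diabetes=y.astype(float))  # perfect separator
        with pytest.raises(ConvergenceError):
            fit_null_logistic(cohort, None, "diabetes")


class TestFixedEffectScoreTest:
    def test_constant_exposure_degenerates(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        cohort = make_cohort(y, diabetes=np.zeros(200))
        xhat_vals = rng.normal(size=200)
        from gxescan.types import PredictedExpression
        xhat = PredictedExpression("g", xhat_vals, 1, 0)
        fit = fit_null_logistic(cohort, xhat, "diabetes")
        res = fixed_effect_score_test(fit, xhat_vals * cohort.exposure("diabetes"))
        assert res.degenerate
        assert res.p_value == 1.0

    def test_strong_burden_interaction_detected(self):
        """A large burden interaction with a binary exposure at n=2000 is
        overwhelmingly detected by the fixed component (median over a few
        genotype/weight realizations)."""
        ps = []
        for seed in range(5):
            sc = SimScenario(n_cases=1000, n_controls=1000, n_genes=1,
                             snps_per_gene=30, weight_sparsity=0.6,
                             exposure="diabetes", tau=0.6, seed=500 + seed)
            g, cohort, wss = simulate_cohort(sc)
            r = misti_core.test_gene(wss[0], g, cohort, "diabetes",
                                     include_sex=True, n_pcs=3)
            ps.append(r.p_fixed)
        assert np.median(ps) < 1e-4


class TestRandomEffectScoreTest:
    def test_column_in_design_is_annihilated(self, small_cohort):
        """A residual-interaction column already in the null design carries no
        score signal after projection."""
        g, cohort, wss = small_cohort
        ws = harmonize_alleles(wss[0], g)
        xhat = predict_expression(ws, g)
        fit = fit_null_logistic(cohort, xhat, "bmi",
                                include_fixed_interaction=True, include_sex=True)
        c = (xhat.values * cohort.exposure("bmi"))[:, None]
        res = random_effect_score_test(fit, c)
        assert res.degenerate or res.p_value > 0.99

    def test_eigenvalues_nonnegative_and_sorted(self, small_cohort):
        g, cohort, wss = small_cohort
        ws = harmonize_alleles(wss[0], g)
        xhat = predict_expression(ws, g)
        fit = fit_null_logistic(cohort, xhat, "bmi",
                                include_fixed_interaction=True, include_sex=True)
        cols = [g.variant_index()[v] for v in ws.variant_ids]
        c = g.dosages[:, cols] * cohort.exposure("bmi")[:, None]
        res = random_effect_score_test(fit, c)
        assert np.all(res.eigenvalues >= 0)
        assert np.all(np.diff(res.eigenvalues) <= 0)
        assert 0 < res.p_value <= 1


class TestMixtureChisqPvalue:
    def test_single_component_matches_chi2_1(self):
        assert mixture_chisq_pvalue(3.841459, [1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_equal_pair_matches_chi2_2(self):
        assert mixture_chisq_pvalue(5.991465, [1.0, 1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_scaled_single_component(self):
        # P(2.5 Z^2 > q) = P(Z^2 > q/2.5)
        q = 7.0
        assert mixture_chisq_pvalue(q, [2.5]) == pytest.approx(chi2.sf(q / 2.5, 1), rel=1e-9)

    def test_matches_monte_carlo(self):
        lam = np.array([2.3, 1.1, 0.4])
        rng = np.random.default_rng(10)
        draws = (rng.standard_normal((2_000_000, 3)) ** 2) @ lam
        for q in (3.0, 8.0, 15.0, 25.0):
            mc = float((draws > q).mean())
            se = np.sqrt(mc * (1 - mc) / draws.size)
            assert abs(mixture_chisq_pvalue(q, lam) - mc) < 3 * se

    def test_monotone_in_q_and_one_at_zero(self):
        lam = [1.7, 0.6, 0.2]
        qs = np.linspace(0, 40, 50)
        ps = [mixture_chisq_pvalue(q, lam) for q in qs]
        assert ps[0] == 1.0
        assert np.all(np.diff(ps) <= 1e-12)

    def test_agrees_across_backends(self):
        """Ruben series and Imhof integration agree where both apply."""
        lam = np.array([3.0, 1.0, 0.5, 0.25])
        for q in (2.0, 10.0, 25.0):
            ruben = misti_core._ruben_pvalue(q, lam)
            imhof, _ = misti_core._imhof_pvalue(q, lam)
            assert ruben == pytest.approx(imhof, abs=5e-6)

    def test_all_zero_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            mixture_chisq_pvalue(1.0, [0.0, 0.0])


class TestCombineComponents:
    def test_no_signal_boundary(self):
        p, w = combine_components(1.0, 1.0)
        assert p == 1.0

    def test_fisher_closed_form(self):
        p, _ = combine_components(0.05, 0.05, method="fisher")
        t = -2 * (np.log(0.05) + np.log(0.05))
        assert t == pytest.approx(11.98293, abs=1e-5)
        assert p == pytest.approx(chi2.sf(t, 4), rel=1e-12)
        assert p == pytest.approx(0.01747, abs=1e-5)

    def test_adaptive_never_beats_best_component_by_free_lunch(self):
        # min-p searching over 5 weights must pay a multiplicity price
        p, w = combine_components(1e-5, 0.3)
        assert p > 1e-5
        assert w == 1.0  # all weight on the fixed component

    def test_invalid_pvalues_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                combine_components(bad, 0.5)

    def test_null_uniformity_of_adaptive_p(self):
        """Adaptive combination of independent uniforms is itself uniform."""
        rng = np.random.default_rng(2024)
        pairs = rng.uniform(size=(20_000, 2))
        ps = np.array([combine_components(a, b)[0] for a, b in pairs])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_symmetric_in_components_up_to_grid(self):
        pa, _ = combine_components(0.01, 0.6)
        pb, _ = combine_components(0.6, 0.01)
        assert pa == pytest.approx(pb, rel=1e-9)  # grid is symmetric around 0.5


class TestGeneLevelInvariances:
    def test_weight_rescaling_leaves_pvalues_unchanged(self, small_cohort):
        g, cohort, wss = small_cohort
        ws = wss[0]
        r1 = misti_core.test_gene(ws, g, cohort, "bmi", include_sex=True)
        ws_scaled = make_weight_set(ws.variant_ids, ws.weights * 7.3,
                                    effect=ws.effect_alleles,
                                    other=ws.other_alleles,
                                    r2=ws.predictive_r2, gene=ws.gene_id)
        r2 = misti_core.test_gene(ws_scaled, g, cohort, "bmi", include_sex=True)
        assert r2.p_fixed == pytest.approx(r1.p_fixed, rel=1e-6)

    def test_allele_flip_leaves_pvalues_unchanged(self, small_cohort):
        """Recoding which allele a weight counts must not move any p-value:
        harmonization negates the weight and complements the dosage, shifting
        x-hat by a constant the intercept absorbs."""
        g, cohort, wss = small_cohort
        ws = wss[0]
        r1 = misti_core.test_gene(ws, g, cohort, "bmi", include_sex=True)
        flipped = make_weight_set(
            ws.variant_ids, ws.weights,
            effect=[ws.other_alleles[0]] + ws.effect_alleles[1:],
            other=[ws.effect_alleles[0]] + ws.other_alleles[1:],
            r2=ws.predictive_r2, gene=ws.gene_id)
        r2 = misti_core.test_gene(flipped, g, cohort, "bmi", include_sex=True)
        assert r2.p_fixed == pytest.approx(r1.p_fixed, rel=1e-5)
        assert r2.p_random == pytest.approx(r1.p_random, rel=1e-5)
        assert r2.p_adaptive == pytest.approx(r1.p_adaptive, rel=1e-5)
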