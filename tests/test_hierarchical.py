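"""Hierarchical Bayesian models: oracles, recovery, invariances, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import recombage as r
from recombage.hierarchical import HierarchicalCrossoverModel, ModelSpec
from recombage.posterior import negbin_logpmf
from recombage.priors import PriorSet

from conftest import make_meioses

class TestModelSpec:
    def test_variant_properties(self):
        spec = ModelSpec("M2*")
        assert spec.model_id == "M2star"
        assert spec.likelihood == "negative_binomial"
        assert spec.age_effect == "common"
        assert spec.hierarchy_level == "cohort_by_configuration"
        assert ModelSpec("M1.2").age_effect == "per_cohort"
        assert ModelSpec("M1").hierarchy_level == "cohort"
        with pytest.raises(ValueError):
            ModelSpec("M3")

    def test_selection_rules(self, nb_meioses):
        table, _, _ = nb_meioses
        fully = r.select_meioses(table, ModelSpec("M2"))
        assert set(fully.configuration) <= {2, 6}
        star = r.select_meioses(table, ModelSpec("M2star"))
        cell_sizes = star.groupby(["cohort", "configuration"]).size()
        assert (cell_sizes >= 20).all()
        assert (star.groupby("parent_id").size() >= 2).all()


class TestConjugateOracle:
    def test_posterior_of_group_mean_matches_closed_form(self):
        # Normal likelihood with known (fixed) variance components and no
        # age signal: mu | y is conjugate normal.
        sigma2_0, tau2_0 = 4.0, 9.0
        m0, s02 = 35.0, 25.0
        rng = np.random.default_rng(12)
        rows = []
        k = 2
        for j in range(40):
            alpha = rng.normal(40.0, np.sqrt(sigma2_0))
            for c in range(k):
                rows.append(("A", f"F{j}", f"P{j}", f"P{j}K{c}", "F",
                             30.0 + 0.001 * c + 0.0001 * j, 2,
                             rng.normal(alpha, np.sqrt(tau2_0))))
        table = make_meioses(rows)
        priors = PriorSet(mu_mean=m0, mu_var=s02)
        model = HierarchicalCrossoverModel(
            table, ModelSpec("M1"), priors=priors, apply_selection=False,
            fixed={"beta": 0.0, "sigma2": sigma2_0, "tau2": tau2_0})
        res = model.fit(n_chains=4, n_draws=2000, seed=3)

        # closed form: parent means are N(mu, sigma2 + tau2/k)
        ybar = table.groupby("parent_id")["n_crossovers"].mean().to_numpy()
        v = sigma2_0 + tau2_0 / k
        post_prec = 1 / s02 + len(ybar) / v
        post_mean = (m0 / s02 + ybar.sum() / v) / post_prec
        post_sd = np.sqrt(1 / post_prec)

        draws = res.get("mu[A]")
        mcse = draws.std(ddof=1) / np.sqrt(res.ess("mu[A]"))
        assert abs(draws.mean() - post_mean) < 3 * mcse
        assert abs(draws.std(ddof=1) - post_sd) < 0.15 * post_sd


class TestGridOracle:
    def test_negbin_posterior_matches_grid_integration(self):
        # Tiny M2-style model with the parent effects pinned to mu
        # (sigma2 fixed at ~0); exact posterior of (beta, mu, omega) by
        # 3-D quadrature over the same likelihood.
        rng = np.random.default_rng(4)
        ages = np.array([22.0, 25.0, 28.0, 31.0, 34.0, 37.0, 40.0, 43.0])
        y = np.array([34, 40, 37, 42, 36, 44, 39, 41], dtype=float)
        rows = [("A", f"F{j // 2}", f"P{j // 2}", f"K{j}", "F", ages[j], 2,
                 int(y[j])) for j in range(8)]
        table = make_meioses(rows)
        m0, s02 = np.log(38.0), 0.25
        priors = PriorSet(mu_mean=m0, mu_var=s02)
        model = HierarchicalCrossoverModel(
            table, ModelSpec("M2"), priors=priors, apply_selection=False,
            fixed={"sigma2": 1e-12})
        res = model.fit(n_chains=4, n_draws=4000, seed=5)

        betas = np.linspace(-0.08, 0.12, 81)
        mus = np.linspace(m0 - 1.2, m0 + 1.2, 81)
        us = np.linspace(0.005, 0.995, 80)  # 1/omega
        B, M, U = np.meshgrid(betas, mus, us, indexing="ij")
        logp = np.zeros_like(B)
        for j in range(8):
            mean = np.exp(B * ages[j] + M)
            omega = 1.0 / U
            a = mean / (omega - 1.0)
            logp += (stats.nbinom.logpmf(y[j], a, U))
        logp += stats.norm.logpdf(B, 0, 1) + stats.norm.logpdf(M, m0, np.sqrt(s02))
        w = np.exp(logp - logp.max())
        w /= w.sum()
        grid_beta = float((w * B).sum())
        grid_mu = float((w * M).sum())
        grid_beta_sd = float(np.sqrt((w * (B - grid_beta) ** 2).sum()))

        mc_beta = res.posterior_mean("beta_age")
        mcse = res.posterior_sd("beta_age") / np.sqrt(res.ess("beta_age"))
        assert abs(mc_beta - grid_beta) < max(4 * mcse, 0.05 * grid_beta_sd)
        assert abs(res.posterior_mean("mu[A]") - grid_mu) < 0.02


class TestPriorPredictive:
    def test_no_data_posterior_equals_prior(self):
        empty = make_meioses([])
        model = HierarchicalCrossoverModel(empty, ModelSpec("M1"),
                                           priors=PriorSet())
        res = model.fit(n_chains=4, n_draws=3000, seed=6)
        beta = res.get("beta_age").ravel()
        assert abs(beta.mean()) < 0.08
        assert abs(beta.std(ddof=1) - 1.0) < 0.08
        q = res.quantile("beta_age", [0.025, 0.975])
        assert np.allclose(q, [-1.96, 1.96], atol=0.15)


class TestParameterRecovery:
    def test_m2_recovers_log_scale_age_effect(self):
        specs = [r.CohortSpec(f"C{i}", {2: 40}) for i in range(3)]
        params = r.default_generative_params(
            specs, model_family="negative_binomial", beta_age=0.004)
        table, _ = r.simulate_cohorts(specs, params, seed=13)
        model = HierarchicalCrossoverModel(table, ModelSpec("M2"))
        res = model.fit(n_chains=2, n_draws=1500, seed=13)
        assert res.max_rhat() < 1.05
        mean, sd = res.posterior_mean("beta_age"), res.posterior_sd("beta_age")
        assert abs(mean - 0.004) < 2.5 * sd

    def test_m2star_matches_m2_on_single_configuration(self):
        specs = [r.CohortSpec(f"C{i}", {2: 25}) for i in range(3)]
        params = r.default_generative_params(specs)
        table, _ = r.simulate_cohorts(specs, params, seed=14)
        res2 = HierarchicalCrossoverModel(table, ModelSpec("M2")).fit(
            n_chains=2, n_draws=1000, seed=1)
        res2s = HierarchicalCrossoverModel(table, ModelSpec("M2star")).fit(
            n_chains=2, n_draws=1000, seed=2)
        m2, m2s = res2.posterior_mean("beta_age"), res2s.posterior_mean("beta_age")
        pooled_sd = res2.posterior_sd("beta_age")
        assert abs(m2 - m2s) < 0.5 * pooled_sd
        lo2, hi2 = res2.quantile("beta_age", [0.025, 0.975])
        lo2s, hi2s = res2s.quantile("beta_age", [0.025, 0.975])
        assert abs((hi2 - lo2) - (hi2s - lo2s)) < 0.35 * (hi2 - lo2)

    def test_partially_informative_meioses_tighten_posterior(self, nb_meioses):
        table, _, _ = nb_meioses
        res_full = HierarchicalCrossoverModel(table, ModelSpec("M2")).fit(
            n_chains=2, n_draws=1000, seed=7)
        res_star = HierarchicalCrossoverModel(table, ModelSpec("M2star")).fit(
            n_chains=2, n_draws=1000, seed=7)
        lo_f, hi_f = res_full.quantile("beta_age", [0.025, 0.975])
        lo_s, hi_s = res_star.quantile("beta_age", [0.025, 0.975])
        assert (hi_s - lo_s) < (hi_f - lo_f)


class TestDeterminismAndExchangeability:
    def test_same_seed_identical_draws(self):
        specs = [r.CohortSpec(f"C{i}", {2: 12}) for i in range(2)]
        params = r.default_generative_params(specs, model_family="normal")
        table, _ = r.simulate_cohorts(specs, params, seed=15)
        model = HierarchicalCrossoverModel(table, ModelSpec("M1"))
        r1 = model.fit(n_chains=2, n_draws=600, seed=9)
        r2 = HierarchicalCrossoverModel(table, ModelSpec("M1")).fit(
            n_chains=2, n_draws=600, seed=9)
        assert np.array_equal(r1.raw_draws, r2.raw_draws)

    def test_row_permutation_leaves_summaries_stable(self):
        specs = [r.CohortSpec(f"C{i}", {2: 15}) for i in range(2)]
        params = r.default_generative_params(specs, model_family="normal")
        table, _ = r.simulate_cohorts(specs, params, seed=16)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r1 = HierarchicalCrossoverModel(table, ModelSpec("M1")).fit(
            n_chains=2, n_draws=1500, seed=10)
        r2 = HierarchicalCrossoverModel(shuffled, ModelSpec("M1")).fit(
            n_chains=2, n_draws=1500, seed=10)
        sd = r1.posterior_sd("beta_age")
        mcse = sd / np.sqrt(r1.ess("beta_age"))
        assert abs(r1.posterior_mean("beta_age")
                   - r2.posterior_mean("beta_age")) < 6 * mcse


class TestSummaries:
    @pytest.fixture()
    def constant_results(self):
        empty = make_meioses([])
        model = HierarchicalCrossoverModel(empty, ModelSpec("M1"),
                                           priors=PriorSet())
        res = model.fit(n_chains=2, n_draws=400, seed=0)
        return model, res

    def test_constant_draws_quantiles(self, constant_results):
        model, res = constant_results
        res.raw_draws = np.full_like(res.raw_draws, 0.1)
        row = res.summary_row("beta_age")
        assert all(np.isclose(row[q], 0.1)
                   for q in ("2.5%", "25%", "50%", "75%", "97.5%"))
        assert row["Pr(>0)"] == 1.0

    def test_symmetric_draws(self, constant_results):
        model, res = constant_results
        flat = res.raw_draws.reshape(-1, res.raw_draws.shape[2])
        flat[: len(flat) // 2] = -1.0
        flat[len(flat) // 2:] = 1.0
        assert res.prob_positive("beta_age") == 0.5
        assert -1.0 <= res.quantile("beta_age", 0.5) <= 1.0

    def test_standard_normal_quantile(self):
        draws = np.random.default_rng(1).standard_normal(10**6)
        assert abs(np.quantile(draws, 0.975) - 1.96) < 0.01

    def test_unknown_parameter_rejected(self, constant_results):
        _, res = constant_results
        with pytest.raises(KeyError):
            res.get("nonexistent")

    def test_multiplicative_summary_exponentiates(self):
        specs = [r.CohortSpec(f"C{i}", {2: 12}) for i in range(2)]
        params = r.default_generative_params(specs)
        table, _ = r.simulate_cohorts(specs, params, seed=17)
        res = HierarchicalCrossoverModel(table, ModelSpec("M2")).fit(
            n_chains=2, n_draws=600, seed=11)
        row = res.summary_row("beta_age")
        med_log = res.quantile("beta_age", 0.5)
        assert np.isclose(row["50%"], np.exp(med_log))
        assert row["Pr(>0)"] == res.prob_positive("beta_age")


class TestConversions:
    def test_fig4_style_additive_equivalents(self):
        assert round(r.multiplicative_to_additive(0.985, 38), 2) == -0.57
        assert round(r.multiplicative_to_additive(1.013, 38), 2) == 0.49
        assert r.multiplicative_to_additive(1.0, 38) == 0.0

    def test_ten_year_percent_increase(self):
        assert round(r.multiplicative_to_percent(1.00098, 10), 2) == 0.98
        assert r.multiplicative_to_percent(1.0, 10) == 0.0
        val = r.multiplicative_to_percent(1.00213, 10)
        assert abs(val - 2.1) < 0.06

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            r.multiplicative_to_percent(0.0)
        with pytest.raises(ValueError):
            r.multiplicative_to_additive(-1.0)


class TestConvergenceRule:
    def test_unattainable_threshold_raises_with_report(self):
        specs = [r.CohortSpec(f"C{i}", {2: 10}) for i in range(2)]
        params = r.default_generative_params(specs, model_family="normal")
        table, _ = r.simulate_cohorts(specs, params, seed=18)
        model = HierarchicalCrossoverModel(table, ModelSpec("M1"))
        with pytest.raises(r.ConvergenceError, match="R-hat"):
            model.fit(n_chains=2, n_draws=200, seed=0,
                      rhat_threshold=1.0000001, max_extensions=0)

    def test_extension_appends_draws(self):
        specs = [r.CohortSpec(f"C{i}", {2: 10}) for i in range(2)]
        params = r.default_generative_params(specs, model_family="normal")
        table, _ = r.simulate_cohorts(specs, params, seed=18)
        model = HierarchicalCrossoverModel(table, ModelSpec("M1"))
        res = model.fit(n_chains=2, n_draws=300, seed=0,
                        rhat_threshold=1.005, max_extensions=8,
                        extension_draws=300)
        assert res.max_rhat() <= 1.005
        assert res.n_draws_per_chain == 150 + 300 * res.n_extensions


class TestRobustnessReruns:
    def test_strong_signal_survives_all_prior_relaxations(self):
        specs = [r.CohortSpec(f"C{i}", {2: 12, 4: 12}) for i in range(2)]
        params = r.default_generative_params(
            specs, model_family="negative_binomial", beta_age=0.02)
        table, _ = r.simulate_cohorts(specs, params, seed=19)
        reruns = r.robustness_reruns(
            table, ModelSpec("M2star"), n_chains=2, n_draws=1000, seed=21)
        assert set(reruns) == {"beta", "mu", "sigma", "omega"}
        for name, res in reruns.items():
            assert res.prob_positive("beta_age") >= 0.99, name

    def test_beta_prior_insensitivity_at_strong_signal(self):
        specs = [r.CohortSpec(f"C{i}", {2: 12, 4: 12}) for i in range(2)]
        params = r.default_generative_params(
            specs, model_family="negative_binomial", beta_age=0.02)
        table, _ = r.simulate_cohorts(specs, params, seed=19)
        base = HierarchicalCrossoverModel(table, ModelSpec("M2star")).fit(
            n_chains=2, n_draws=800, seed=22)
        relaxed = r.robustness_reruns(
            table, ModelSpec("M2star"), parameters=("beta",),
            n_chains=2, n_draws=800, seed=22)["beta"]
        diff = abs(base.quantile("beta_age", 0.5)
                   - relaxed.quantile("beta_age", 0.5))
        assert diff < 0.5 * base.posterior_sd("beta_age")

    def test_non_star_spec_rejected(self, nb_meioses):
        table, _, _ = nb_meioses
        with pytest.raises(ValueError, match="M2star"):
            r.robustness_reruns(table, ModelSpec("M2"))
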