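import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from rrtsurvey.prevalence import (
    CellPosterior,
    ContrastSummary,
    GridPosterior,
    IdentifiabilityWarning,
    McmcConfig,
    MixtureModelSpec,
    contrast_strata,
    fit_cell_gibbs,
    fit_prevalence_gibbs,
    grid_posterior_oracle,
    mom_estimate,
    summarize_posterior,
)
from conftest import simulate_masked_binary

FAST = McmcConfig(n_burnin=2000, n_samples=4000, n_chains=2, seed=17)


class TestMomEstimate:
    def test_direct_question_limit(self):
        assert mom_estimate(0.3, 1.0, 0.4).estimate == pytest.approx(0.3)

    def test_boundary_hits_zero(self):
        p_s, pi_ns = 2 / 3, 0.4
        r = mom_estimate((1 - p_s) * pi_ns, p_s, pi_ns)
        assert r.estimate == pytest.approx(0.0)
        assert not r.clipped

    def test_clipping_flagged(self):
        r = mom_estimate(0.05, 2 / 3, 0.9)
        assert r.estimate == 0.0 and r.clipped and r.raw < 0

    def test_p_s_zero_rejected(self):
        with pytest.raises(ValueError, match="p_s"):
            mom_estimate(0.5, 0.0, 0.3)

    def test_monte_carlo_inversion_oracle(self, rng):
        # p_s=2/3, pi_ns=0.4, p_obs=0.6 implies pi_s = 0.7; simulate at that
        # truth and re-invert.
        p_s, pi_ns = 2 / 3, 0.4
        implied = mom_estimate(0.6, p_s, pi_ns).estimate
        assert implied == pytest.approx(0.7, abs=1e-12)
        y = simulate_masked_binary(10**6, implied, pi_ns, p_s, rng)
        back = mom_estimate(y.mean(), p_s, pi_ns).estimate
        assert back == pytest.approx(implied, abs=0.005)

    def test_consistency_over_replicates(self, rng):
        # spec invariant: mean over 500 replicates of n=2000 within 0.01
        p_s, pi_s, pi_ns, n = 2 / 3, 0.35, 0.5, 2000
        p1 = p_s * pi_s + (1 - p_s) * pi_ns
        p_obs = rng.binomial(n, p1, size=500) / n
        ests = np.clip((p_obs - (1 - p_s) * pi_ns) / p_s, 0, 1)
        assert abs(ests.mean() - pi_s) < 0.01


class TestGridOracle:
    def test_prior_recovery_without_data(self):
        spec = MixtureModelSpec(p_s=0.5, pi_ns_value=0.3)
        post = grid_posterior_oracle(np.array([], dtype=int), spec)
        assert post.mean == pytest.approx(0.5, abs=1e-6)

    def test_conjugate_closed_form(self):
        # p_s=1, 7 of 10 yes, Beta(1,1) prior -> Beta(8,4), mean 8/12
        spec = MixtureModelSpec(p_s=1.0, pi_ns_value=0.0)
        y = np.array([1] * 7 + [0] * 3)
        post = grid_posterior_oracle(y, spec)
        assert post.mean == pytest.approx(8 / 12, abs=1e-4)
        lo, hi = post.interval()
        assert lo == pytest.approx(stats.beta.ppf(0.025, 8, 4), abs=2e-3)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 8, 4), abs=2e-3)

    def test_mass_normalized(self, rng):
        spec = MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.4)
        y = simulate_masked_binary(100, 0.5, 0.4, 2 / 3, rng)
        post = grid_posterior_oracle(y, spec)
        assert abs(post.mass.sum() - 1.0) < 1e-12

    def test_resolution_floor(self):
        spec = MixtureModelSpec(p_s=0.5, pi_ns_value=0.3)
        with pytest.raises(ValueError, match="grid_size"):
            grid_posterior_oracle(np.array([1, 0]), spec, grid_size=49)

    def test_beta_prior_mode_marginalizes(self, rng):
        with pytest.warns(IdentifiabilityWarning):
            spec = MixtureModelSpec(p_s=2 / 3, pi_ns_mode="beta_prior")
        y = simulate_masked_binary(150, 0.5, 0.3, 2 / 3, rng)
        post = grid_posterior_oracle(y, spec, grid_size=400)
        assert abs(post.mass.sum() - 1.0) < 1e-12
        assert 0.0 < post.mean < 1.0


class TestGibbs:
    def test_all_zero_responses_shrink_to_zero(self):
        spec = MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.0)
        post = fit_cell_gibbs(np.zeros(200, dtype=int), spec, FAST)
        assert post.summary.mean < 0.05

    def test_direct_question_matches_conjugate(self, rng):
        y = rng.binomial(1, 0.4, size=120)
        n1 = int(y.sum())
        spec = MixtureModelSpec(p_s=1.0, pi_ns_value=0.0)
        post = fit_cell_gibbs(y, spec, FAST)
        conj = stats.beta(1 + n1, 1 + 120 - n1)
        assert post.summary.mean == pytest.approx(conj.mean(), abs=0.01)
        assert post.summary.cri_low == pytest.approx(conj.ppf(0.025), abs=0.02)
        assert post.summary.cri_high == pytest.approx(conj.ppf(0.975), abs=0.02)

    def test_oracle_equivalence_single_cell(self, rng):
        y = simulate_masked_binary(300, 0.5, 0.2, 2 / 3, rng)
        spec = MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.2)
        post = fit_cell_gibbs(y, spec, FAST)
        oracle = grid_posterior_oracle(y, spec)
        assert abs(post.summary.mean - oracle.mean) <= 0.01

    def test_masking_degrades_information(self, rng):
        latent = rng.binomial(1, 0.5, size=200)
        mask = rng.random(200) >= 2 / 3
        unrelated = rng.binomial(1, 0.3, size=200)
        y_masked = np.where(mask, unrelated, latent)
        direct = fit_cell_gibbs(latent, MixtureModelSpec(p_s=1.0, pi_ns_value=0.0), FAST)
        masked = fit_cell_gibbs(y_masked, MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.3), FAST)
        width = lambda s: s.cri_high - s.cri_low
        assert width(masked.summary) >= width(direct.summary)

    def test_empty_cell_rejected(self):
        spec = MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.3)
        with pytest.raises(ValueError, match="empty"):
            fit_cell_gibbs(np.array([], dtype=int), spec, FAST)

    def test_grouped_fit_covers_all_cells(self, rng):
        rows = []
        for mun in ("manaus", "carauari"):
            for season in ("dry", "wet"):
                for _ in range(30):
                    rows.append(
                        {
                            "municipality": mun,
                            "urbanization": "urban",
                            "item_domain": "chelonians:trade",
                            "season": season,
                            "use": int(rng.random() < 0.5),
                        }
                    )
        df = pd.DataFrame(rows)
        spec = MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.5)
        small = McmcConfig(n_burnin=500, n_samples=500, n_chains=2, seed=3)
        cells = fit_prevalence_gibbs(df, spec, small)
        assert len(cells) == 4
        for post in cells.values():
            assert post.n == 30
            assert 0.0 <= post.summary.mean <= 1.0

    def test_per_cell_seeds_differ_but_rerun_is_identical(self, rng):
        y = simulate_masked_binary(100, 0.5, 0.3, 2 / 3, rng)
        spec = MixtureModelSpec(p_s=2 / 3, pi_ns_value=0.3)
        a = fit_cell_gibbs(y, spec, FAST, cell=("a",))
        a2 = fit_cell_gibbs(y, spec, FAST, cell=("a",))
        b = fit_cell_gibbs(y, spec, FAST, cell=("b",))
        np.testing.assert_array_equal(a.pi_s, a2.pi_s)
        assert not np.array_equal(a.pi_s, b.pi_s)


class TestSummarize:
    def test_degenerate_chain(self):
        s = summarize_posterior(np.full((2, 100), 0.42))
        assert s.mean == s.median == s.cri_low == s.cri_high == 0.42

    def test_normal_quantile_oracle(self, rng):
        draws = rng.standard_normal((2, 50_000))
        s = summarize_posterior(draws)
        assert s.cri_low == pytest.approx(-1.96, abs=0.05)
        assert s.cri_high == pytest.approx(1.96, abs=0.05)
        assert s.rhat == pytest.approx(1.0, abs=0.01)

    def test_percent_format(self):
        from rrtsurvey.prevalence import PosteriorSummary

        s = PosteriorSummary(mean=0.21, median=0.2, cri_low=0.07, cri_high=0.34, rhat=1.0, ess=1e4)
        assert s.format_percent() == "21% [95% CI 7–34]"

    def test_single_chain_rhat_unavailable(self, rng):
        s = summarize_posterior(rng.standard_normal(5000))
        assert np.isnan(s.rhat)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            summarize_posterior(np.array([1.0, np.inf]))


class TestContrast:
    def test_point_masses(self):
        a = np.full((2, 50), 0.8)
        b = np.full((2, 50), 0.2)
        c = contrast_strata(a, b)
        assert c.difference.mean == pytest.approx(0.6)
        assert c.p_a_gt_b == 1.0 and c.differs

    def test_self_comparison(self, rng):
        a = rng.beta(2, 2, size=(2, 500))
        c = contrast_strata(a, a)
        assert c.difference.mean == 0.0 and not c.differs

    def test_independent_beta_closed_form(self, rng):
        a = rng.beta(8, 4, size=(2, 40_000))
        b = rng.beta(4, 8, size=(2, 40_000))
        c = contrast_strata(a, b, paired=False)
        # deterministic numeric oracle for P(A > B)
        exact, _ = integrate.quad(
            lambda y: stats.beta.pdf(y, 4, 8) * stats.beta.sf(y, 8, 4), 0, 1
        )
        assert c.p_a_gt_b == pytest.approx(exact, abs=0.01)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contrast_strata(np.empty((1, 0)), np.empty((1, 0)))

    def test_paired_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal shapes"):
            contrast_strata(rng.random((2, 10)), rng.random((2, 11)))


class TestSpecValidation:
    def test_beta_prior_mode_warns_about_ridge(self):
        with pytest.warns(IdentifiabilityWarning, match="ridge"):
            MixtureModelSpec(p_s=2 / 3, pi_ns_mode="beta_prior")

    def test_known_mode_requires_value(self):
        with pytest.raises(ValueError, match="pi_ns_value"):
            MixtureModelSpec(p_s=0.5, pi_ns_mode="known", pi_ns_value=None)

    def test_p_s_bounds(self):
        with pytest.raises(ValueError, match="p_s"):
            MixtureModelSpec(p_s=0.0, pi_ns_value=0.3)

    def test_mcmc_defaults(self):
        mc = McmcConfig(seed=1)
        assert (mc.n_burnin, mc.n_samples) == (50_000, 25_000)

    def test_bad_prior_rejected(self):
        with pytest.raises(ValueError, match="pi_s_prior"):
            MixtureModelSpec(p_s=0.5, pi_ns_value=0.3, pi_s_prior=(0.0, 1.0))
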