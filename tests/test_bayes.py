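import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from optimet.bayes import Chains, MCMCSettings, PriorSpec, log_posterior, posterior_mode, run_mcmc
from optimet.cgm import DEFAULT_BOUNDS, ParameterBounds, simulate_heading, simulate_phenotypes
from optimet.environments import Site, WeatherSeries, build_environments
from optimet.evaluation import nrmse


def _constant_env(temp=20.0, latitude=0.0):
    sid = f"c{temp:g}"
    dates = pd.date_range("2001-01-01", periods=420)
    ws = WeatherSeries(sid, dates, np.full(420, float(temp)))
    return build_environments(
        [Site(sid, "const", latitude)], [dt.date(2001, 1, 15)], {sid: ws}, 300
    )[0]


@pytest.fixture(scope="module")
def informative_design(france_envs):
    ids = {e.env_id: e for e in france_envs}
    return [
        ids["s7:2001-09-15"],
        ids["s3:2001-09-15"],
        ids["s7:2001-11-15"],
        ids["s6:2002-03-15"],
    ]


class TestLogPosterior:
    def test_outside_uniform_support_is_minus_inf(self):
        env = _constant_env()
        obs = pd.DataFrame({"env_id": [env.env_id], "heading_days": [57.5]})
        assert log_posterior([0.02, 0.5, 100.0], 4.0, obs, [env]) == -math.inf
        assert log_posterior([0.005, 0.5, 130.0], 4.0, obs, [env]) == -math.inf

    def test_perfect_fit_single_obs_unit_variance(self):
        env = _constant_env()
        theta = [0.01, 0.0, 100.0]
        obs = pd.DataFrame({"env_id": [env.env_id], "heading_days": [simulate_heading(theta, env)]})
        priors = PriorSpec()
        lp = log_posterior(theta, 1.0, obs, [env], priors)
        assert lp - priors.log_ig(1.0) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_independent_density_sum_on_three_obs(self):
        env = _constant_env()
        theta = [0.004, 0.6, 95.0]
        f = simulate_heading(theta, env)
        y = np.array([f - 1.0, f + 0.5, f + 2.0])
        obs = pd.DataFrame({"env_id": env.env_id, "heading_days": y})
        priors = PriorSpec()
        sigma2 = 3.0
        expected = stats.norm.logpdf(y, loc=f, scale=math.sqrt(sigma2)).sum()
        expected += stats.invgamma.logpdf(sigma2, priors.ig_shape, scale=priors.ig_scale)
        assert log_posterior(theta, sigma2, obs, [env], priors) == pytest.approx(expected)

    def test_empty_observations_raise(self):
        env = _constant_env()
        with pytest.raises(ValueError):
            log_posterior([0.005, 0.5, 100.0], 1.0, pd.DataFrame(columns=["env_id", "heading_days"]), [env])


class TestPosteriorMode:
    def test_constant_chain_returns_the_constant(self):
        assert posterior_mode(np.full(500, 3.7)) == 3.7

    def test_gaussian_sample_mode_near_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10.0, 2.0, 50_000)
        assert abs(posterior_mode(x) - x.mean()) < 0.05 * x.std()

    def test_bimodal_sample_returns_heavier_mode(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.2, 0.03, 8000), rng.normal(0.8, 0.03, 2000)])
        assert posterior_mode(x, support=(0.0, 1.0)) == pytest.approx(0.2, abs=0.05)

    def test_boundary_mode_is_not_pulled_inward(self):
        rng = np.random.default_rng(2)
        x = np.clip(rng.normal(1.0, 0.15, 20_000), 0.0, 1.0)
        assert posterior_mode(x, support=(0.0, 1.0)) > 0.9

    def test_too_few_draws_raise(self):
        with pytest.raises(ValueError):
            posterior_mode(np.arange(50.0))


class TestRunMCMC:
    def test_retained_draw_count_and_shapes(self, qtl_truth_20, informative_design):
        truth = qtl_truth_20[0].true_values.iloc[:4]
        phenos = simulate_phenotypes(truth, informative_design, K=1, noise_sd=2.0, seed=0)
        chains = run_mcmc(
            phenos, informative_design, settings=MCMCSettings(n_iter=2000, burn_in=100, seed=0)
        )
        assert chains.n_retained == 1900
        assert chains.draws.shape == (2000, 4 * 3 + 1)
        assert set(chains.genotype_ids) == set(truth.index)
        assert 0.05 < chains.acceptance["theta"] < 0.9

    def test_same_seed_gives_bit_identical_chains(self, qtl_truth_20, informative_design):
        truth = qtl_truth_20[0].true_values.iloc[:3]
        phenos = simulate_phenotypes(truth, informative_design, K=1, noise_sd=2.0, seed=1)
        kwargs = dict(settings=MCMCSettings(n_iter=500, burn_in=100, seed=7))
        a = run_mcmc(phenos, informative_design, **kwargs)
        b = run_mcmc(phenos, informative_design, **kwargs)
        assert np.array_equal(a.draws, b.draws)

    def test_zero_noise_recovery_within_two_percent(self, informative_design):
        truth = pd.DataFrame(
            [[0.004, 0.6, 95.0], [0.007, 0.3, 110.0], [0.002, 0.8, 85.0]],
            columns=["VAI", "SLDL", "Phyl"],
            index=["a", "b", "c"],
        )
        phenos = simulate_phenotypes(truth, informative_design, K=1, noise_sd=0.0, seed=0)
        chains = run_mcmc(
            phenos,
            informative_design,
            settings=MCMCSettings(n_iter=6000, burn_in=2000, proposal_frac=0.01, seed=1),
        )
        err = (chains.estimates() - truth).abs() / DEFAULT_BOUNDS.ranges
        assert (err.to_numpy() < 0.02).all()

    def test_recovery_beats_prior_guessing_and_improves_with_less_noise(
        self, qtl_truth_20, informative_design
    ):
        truth = qtl_truth_20[0].true_values
        ranges = dict(zip(DEFAULT_BOUNDS.names, DEFAULT_BOUNDS.ranges))
        errs = {}
        for noise in (2.0, 1.0):
            phenos = simulate_phenotypes(truth, informative_design, K=1, noise_sd=noise, seed=2)
            chains = run_mcmc(
                phenos, informative_design, settings=MCMCSettings(n_iter=4000, burn_in=500, seed=3)
            )
            errs[noise] = nrmse(chains.estimates(), truth, ranges)
        # 0.289 is the RMSE of guessing uniformly at random within the bounds
        assert (errs[2.0] < 0.289).all()
        assert (errs[1.0] < errs[2.0]).all()

    def test_sigma2_posterior_concentrates_near_truth(self, qtl_truth_20, informative_design):
        truth = qtl_truth_20[0].true_values
        phenos = simulate_phenotypes(truth, informative_design, K=3, noise_sd=2.0, seed=4)
        chains = run_mcmc(
            phenos, informative_design, settings=MCMCSettings(n_iter=4000, burn_in=500, seed=5)
        )
        post_mean = chains.sigma2_chain().mean()
        assert 4.0 / 1.5 < post_mean < 4.0 * 1.5

    def test_conjugate_gibbs_matches_analytic_linear_toy(self):
        # pin VAI and SLDL to (numerically) zero: the crop model is then
        # linear in Phyl at constant temperature and the posterior has the
        # Normal-Inverse-Gamma closed form
        env = _constant_env(20.0)
        bounds = ParameterBounds(lower=(0.0, 0.0, 80.0), upper=(1e-9, 1e-9, 120.0))
        rng = np.random.default_rng(5)
        n = 30
        y = (150 + 10 * 100.0) / 20 + rng.normal(0, 1.5, n)
        phenos = pd.DataFrame(
            {"genotype_id": "g1", "env_id": env.env_id, "rep": np.arange(n) + 1, "heading_days": y}
        )
        priors = PriorSpec(bounds=bounds)
        chains = run_mcmc(
            phenos,
            [env],
            priors,
            MCMCSettings(n_iter=8000, burn_in=2000, seed=2, variance_sampler="gibbs"),
        )
        phyl = chains.theta_chain("g1", "Phyl")
        sig2 = chains.sigma2_chain().ravel()
        slope, intercept = 10 / 20, 150 / 20
        phyl_hat = (y.mean() - intercept) / slope
        rss = np.sum((y - y.mean()) ** 2)
        a_post = priors.ig_shape + (n - 1) / 2
        b_post = priors.ig_scale + rss / 2
        sig2_mean = b_post / (a_post - 1)
        assert phyl.mean() == pytest.approx(phyl_hat, abs=0.15)
        assert sig2.mean() == pytest.approx(sig2_mean, rel=0.10)
        assert phyl.std() == pytest.approx(math.sqrt(sig2_mean) / (slope * math.sqrt(n)), rel=0.15)

    def test_heteroscedastic_variances_track_env_noise(self, qtl_truth_20):
        truth = qtl_truth_20[0].true_values.iloc[:10]
        quiet, noisy = _constant_env(18.0), _constant_env(12.0)
        p1 = simulate_phenotypes(truth, [quiet], K=4, noise_sd=1.0, seed=6)
        p2 = simulate_phenotypes(truth, [noisy], K=4, noise_sd=4.0, seed=7)
        phenos = pd.concat([p1, p2], ignore_index=True)
        chains = run_mcmc(
            phenos,
            [quiet, noisy],
            PriorSpec(heteroscedastic=True),
            MCMCSettings(n_iter=3000, burn_in=500, seed=8),
        )
        assert chains.n_var == 2
        means = chains.sigma2_chain().mean(axis=0)
        by_env = dict(zip(chains.env_ids, means))
        assert by_env[noisy.env_id] > 4 * by_env[quiet.env_id]

    def test_unobserved_genotype_rejected(self, informative_design):
        phenos = pd.DataFrame(
            {"genotype_id": [], "env_id": [], "rep": [], "heading_days": []}
        )
        with pytest.raises(ValueError):
            run_mcmc(phenos, informative_design)


class TestChainsContainer:
    def test_long_frame_round_trip(self, qtl_truth_20, informative_design):
        truth = qtl_truth_20[0].true_values.iloc[:2]
        phenos = simulate_phenotypes(truth, informative_design, K=1, noise_sd=2.0, seed=9)
        chains = run_mcmc(
            phenos, informative_design, settings=MCMCSettings(n_iter=300, burn_in=150, seed=9)
        )
        frame = chains.to_long_frame(retained_only=True)
        assert len(frame) == chains.n_retained * chains.draws.shape[1]
        one = frame[frame.name == f"{chains.genotype_ids[0]}:VAI"]
        assert np.array_equal(one.value.to_numpy(), chains.theta_chain(chains.genotype_ids[0], "VAI"))
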