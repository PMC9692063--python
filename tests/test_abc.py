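"""Tests for the hierarchical Gibbs ABC machinery.

The likelihood-free pieces are validated against tractable oracles: the
Gaussian-kernel weight against a numeric convolution integral, the MH
machinery against the analytic tolerance-broadened conjugate posterior of a
Gaussian pseudo-model, and the population step against closed-form
normal-inverse-Wishart results.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from lv05abc.abc import (
    ABCConfig,
    NIWPrior,
    PosteriorChains,
    CueRetrievalABC,
    ToleranceError,
    abc_weight_estimate,
    kernel_weight,
    run_abc_mh,
    run_gibbs_abc,
    simulate_summaries_batch,
    summarize_posterior,
    update_individual,
    update_population,
)
from lv05abc.populations import PopulationParams, sample_population, simulate_observed_dataset
from lv05abc.retrieval import LV05Config, ParticipantParams, predict_summaries


def _fast_abc(**kw):
    kw.setdefault("n_sim", 8)
    kw.setdefault("n_trials_sim", 32)
    kw.setdefault("iterations", 40)
    kw.setdefault("burnin", 10)
    return ABCConfig(**kw)


class TestKernelWeight:
    def test_closed_form_points(self):
        assert kernel_weight(0.0, 5.0) == 1.0
        assert kernel_weight(5.0, 5.0) == pytest.approx(np.exp(-0.5))

    def test_strictly_decreasing(self):
        d = np.linspace(0, 30, 50)
        w = kernel_weight(d, 5.0)
        assert (np.diff(w) < 0).all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_weight(-1.0, 5.0)
        with pytest.raises(ValueError):
            kernel_weight(1.0, 0.0)


class TestWeightEstimate:
    def test_noise_free_exact_match_gives_weight_one(self):
        cfg = LV05Config(sigma=0.0, n_trials=10)
        p = ParticipantParams(LF=0.2, CW=2.0)
        pred = predict_summaries(p, cfg, seed=0)
        tbase = 120.0
        y = {"mean_rt_ms": pred.mean_rt_ms + tbase, "effect_ms": pred.effect_ms}
        w = abc_weight_estimate(p, y, cfg, _fast_abc(), tbase=tbase, seed=1)
        assert w == 1.0

    def test_weight_in_unit_interval(self):
        cfg = LV05Config()
        p = ParticipantParams(LF=0.2, CW=1.5)
        y = {"mean_rt_ms": 300.0, "effect_ms": -20.0}
        w = abc_weight_estimate(p, y, cfg, _fast_abc(), tbase=0.0, seed=2)
        assert 0.0 <= w <= 1.0

    def test_matches_convolution_oracle_on_gaussian_pseudo_model(self):
        # summaries ~ Normal(theta, s^2): the expected kernel weight is the
        # convolution integral of kernel x model density, computed here by
        # brute-force quadrature
        theta, s, delta, y = 2.0, 3.0, 4.0, 5.0
        oracle, _ = integrate.quad(
            lambda x: np.exp(-((x - y) ** 2) / (2 * delta**2)) * stats.norm.pdf(x, theta, s),
            -40,
            40,
        )
        rng = np.random.default_rng(7)
        n_sim = 200_000
        sims = theta + s * rng.standard_normal(n_sim)
        w = np.exp(-((sims - y) ** 2) / (2 * delta**2))
        assert w.mean() == pytest.approx(oracle, abs=3 * w.std() / np.sqrt(n_sim))


class TestUpdateIndividual:
    POP = PopulationParams(mu_LF=0.2, mu_CW=2.0, sd_LF=0.05, sd_CW=0.5, rho=0.0)

    def test_identical_proposal_always_accepted(self):
        cfg = LV05Config()
        abc = _fast_abc(proposal_sd_lf=0.0, proposal_sd_cw=0.0)
        y = {"mean_rt_ms": 150.0, "effect_ms": -10.0}
        upd = update_individual(
            ParticipantParams(0.2, 1.5), y, self.POP, 0.0, cfg, abc, seed=3
        )
        assert upd.accepted and upd.theta == ParticipantParams(0.2, 1.5)

    def test_accepted_states_stay_in_domain(self):
        cfg = LV05Config()
        abc = _fast_abc(proposal_sd_lf=0.3, proposal_sd_cw=3.0)
        y = {"mean_rt_ms": 120.0, "effect_ms": -15.0}
        theta = ParticipantParams(0.15, 1.01)
        for seed in range(40):
            upd = update_individual(theta, y, self.POP, 0.0, cfg, abc, seed=seed)
            theta = upd.theta
            assert theta.LF > 0 and theta.CW >= 1

    def test_long_run_matches_broadened_conjugate_posterior(self):
        # Gaussian pseudo-model x ~ N(theta, s^2) with prior N(m0, v0^2):
        # the ABC target is the conjugate posterior with data variance
        # broadened to s^2 + delta^2
        s, delta, y = 10.0, 8.0, 5.0
        m0, v0 = 0.0, 20.0
        draws, acc = run_abc_mh(
            observed=[y],
            simulate=lambda th, n, rng: th[0] + s * rng.standard_normal((n, 1)),
            prior_logpdf=lambda th: -0.5 * ((th[0] - m0) / v0) ** 2,
            init=[0.0],
            proposal_sd=[25.0],
            delta=[delta],
            n_sim=200,
            iterations=40_000,
            burnin=2_000,
            seed=11,
        )
        var_b = 1.0 / (1.0 / v0**2 + 1.0 / (s**2 + delta**2))
        mean_b = var_b * (y / (s**2 + delta**2) + m0 / v0**2)
        assert 0.15 < acc < 0.6
        assert draws.mean() == pytest.approx(mean_b, abs=0.05 * np.sqrt(var_b) * 4)
        assert draws.std() == pytest.approx(np.sqrt(var_b), rel=0.05)


class TestUpdatePopulation:
    def test_identical_draws_concentrate_posterior_mean(self):
        abc = ABCConfig()
        thetas = np.tile([0.2, 2.0], (200, 1))
        rng = np.random.default_rng(0)
        draws = np.array(
            [
                [
                    (p := update_population(thetas, abc, rng)).mu_LF,
                    p.mu_CW,
                ]
                for _ in range(1000)
            ]
        )
        assert draws[:, 0].mean() == pytest.approx(0.2, rel=0.01)
        assert draws[:, 1].mean() == pytest.approx(2.0, rel=0.01)

    def test_prior_predictive_moments(self):
        prior = NIWPrior(mu0=(0.3, 2.0), kappa0=2.0, nu0=6.0, scale=((0.02, 0.0), (0.0, 1.0)))
        abc = ABCConfig(prior_pop=prior)
        rng = np.random.default_rng(1)
        pops = [update_population(np.empty((0, 2)), abc, rng) for _ in range(4000)]
        mu = np.array([[p.mu_LF, p.mu_CW] for p in pops])
        var = np.array([[p.sd_LF**2, p.sd_CW**2] for p in pops])
        # E[Sigma] = scale / (nu0 - dim - 1) for inverse-Wishart
        expected_var = np.diag(prior.scale_arr) / (prior.nu0 - 3)
        assert np.allclose(mu.mean(axis=0), prior.mu0_arr, rtol=0.05, atol=0.01)
        assert np.allclose(var.mean(axis=0), expected_var, rtol=0.15)

    def test_every_draw_valid(self):
        abc = ABCConfig()
        rng = np.random.default_rng(2)
        thetas = np.column_stack([rng.uniform(0.1, 0.3, 20), rng.uniform(1, 3, 20)])
        for _ in range(200):
            p = update_population(thetas, abc, rng)
            assert -1 < p.rho < 1 and p.sd_LF >= 0 and p.sd_CW >= 0

    def test_singular_scale_raises(self):
        abc = ABCConfig(prior_pop=NIWPrior(scale=((0.0, 0.0), (0.0, 0.0))))
        thetas = np.tile([0.2, 2.0], (5, 1))  # zero scatter + zero prior scale
        with pytest.raises(np.linalg.LinAlgError):
            update_population(thetas, abc, np.random.default_rng(3))


@pytest.fixture(scope="module")
def small_dataset():
    pop = PopulationParams(mu_LF=0.2, mu_CW=1.8, sd_LF=0.03, sd_CW=0.4, rho=-0.3)
    sample = sample_population(pop, 6, seed=42)
    cfg = LV05Config(n_trials=20_000)
    return simulate_observed_dataset(
        sample, cfg, noise_se_ms=5.0, dataset_id="toy", dependency="agreement", seed=43
    ).summaries


class TestGibbsSampler:
    def test_parameter_count_is_2n_plus_5(self, small_dataset):
        abc = _fast_abc(seed=1)
        chains = run_gibbs_abc(small_dataset, LV05Config(), abc)
        n = small_dataset.shape[0]
        assert chains.n_model_params == 2 * n + 5
        # tbase is a logged nuisance on top of the 2n + 5 model parameters
        assert chains.draw_matrix().shape[1] == 2 * n + 5 + 1
        assert chains.n_kept == abc.iterations - abc.burnin

    def test_same_seed_identical_chains(self, small_dataset):
        abc = _fast_abc(seed=7)
        a = run_gibbs_abc(small_dataset, LV05Config(), abc)
        b = run_gibbs_abc(small_dataset, LV05Config(), abc)
        assert np.array_equal(a.participant_draws, b.participant_draws)
        assert np.array_equal(a.population_draws, b.population_draws)
        assert np.array_equal(a.tbase_draws, b.tbase_draws)

    def test_chain_draws_satisfy_domain_invariants(self, small_dataset):
        chains = run_gibbs_abc(small_dataset, LV05Config(), _fast_abc(seed=3, iterations=80))
        assert (chains.participant_draws[..., 0] > 0).all()
        assert (chains.participant_draws[..., 1] >= 1).all()
        assert (np.abs(chains.population_draws[:, 4]) < 1).all()
        assert (chains.population_draws[:, 2:4] >= 0).all()

    def test_too_small_tolerance_raises(self, small_dataset):
        far = small_dataset.copy()
        far["mean_rt_ms"] += 5000.0  # far outside any simulated RT
        abc = _fast_abc(seed=4, delta_rt_ms=0.01, delta_eff_ms=0.01)
        with pytest.raises(ToleranceError, match="increase delta"):
            run_gibbs_abc(far, LV05Config(), abc)

    def test_fewer_than_two_participants_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="2 participants"):
            run_gibbs_abc(small_dataset.iloc[:1], LV05Config(), _fast_abc())

    def test_mixed_blocks_rejected(self, small_dataset):
        other = small_dataset.copy()
        other["dataset_id"] = "other"
        both = pd.concat([small_dataset, other])
        with pytest.raises(ValueError, match="one dataset"):
            run_gibbs_abc(both, LV05Config(), _fast_abc())


class TestSummaries:
    def _chains(self, pop_draws, n_participants=2):
        m = pop_draws.shape[0]
        return PosteriorChains(
            participant_ids=[f"P{j}" for j in range(n_participants)],
            participant_draws=np.full((m, n_participants, 2), [0.2, 1.5]),
            population_draws=pop_draws,
            tbase_draws=np.zeros(m),
            acceptance_rates={},
            zero_zero_events=0,
            model_config=LV05Config(),
            abc_config=ABCConfig(),
        )

    def test_constant_chain_zero_width(self):
        pop = np.tile([0.2, 2.0, 0.03, 0.5, -0.3], (50, 1))
        summ = summarize_posterior(self._chains(pop)).set_index("parameter")
        row = summ.loc["rho"]
        assert row["mean"] == pytest.approx(-0.3, abs=1e-12)
        assert row["ci95_low"] == row["ci95_high"] == -0.3
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_interval_brackets_mean_and_matches_sort_oracle(self, rng):
        draws = rng.normal(size=(10_000, 5))
        summ = summarize_posterior(self._chains(draws))
        assert (summ["ci95_low"] <= summ["mean"] + 1e-12).all()
        assert (summ["mean"] <= summ["ci95_high"] + 1e-12).all()
        srt = np.sort(draws[:, 0])
        assert summ.iloc[0]["ci95_low"] == pytest.approx(srt[249], abs=5e-3)
        assert summ.iloc[0]["ci95_high"] == pytest.approx(srt[9750], abs=5e-3)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="4"):
            summarize_posterior(self._chains(np.zeros((3, 5))))


class TestModelResultsInterface:
    def test_fit_returns_results_with_summary_and_rho(self, small_dataset, tmp_path):
        model = CueRetrievalABC(small_dataset, LV05Config(), _fast_abc(seed=9))
        res = model.fit()
        assert res.rho_draws.shape == (30,)
        summ = res.summary()
        assert set(summ["parameter"]) == {"mu_LF", "mu_CW", "sigma_LF", "sigma_CW", "rho", "tbase"}
        paths = res.write_outputs(tmp_path, "toyfit")
        tidy = pd.read_csv(paths["chains"])
        assert set(tidy.columns) == {"iteration", "parameter", "value"}
        ppc = res.posterior_predictive_effects()
        assert ppc.shape[0] == small_dataset.shape[0]
        assert (ppc["pred_effect_ci95_low"] <= ppc["pred_effect_mean_ms"]).all()
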