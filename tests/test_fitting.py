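"""Parameter estimation: psychometric MLEs, the prior/noise iteration,
particle-filter likelihoods, and the model-closeness test."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from pomcon import M1_PARAMS, ModelParams, TaskConfig, generate_trials, simulate_fixed_duration
from pomcon.fitting import (
    estimate_prior,
    fit_sigma_z,
    fit_utility_ratio,
    fit_wz,
    grid_search_cost_model,
    iterate_prior_noise,
    particle_filter_loglik,
    surebet_prob_zero_cost,
    vuong_test,
)


@pytest.fixture(scope="module")
def m1_trials():
    """5e4 zero-cost trials generated at the M1 reference parameters."""
    trials = generate_trials(TaskConfig(n_trials=50_000, seed=41))
    return simulate_fixed_duration(trials, M1_PARAMS, rng=np.random.default_rng(41))


class TestFitWz:
    def test_recovers_generating_noise_within_two_percent(self, m1_trials):
        result = fit_wz(m1_trials)
        assert result.w_z_hat == pytest.approx(M1_PARAMS.w_z, rel=0.02)
        assert not result.flags
        # observed-information standard error: truth within ~3 s.e.
        assert result.se is not None and 0 < result.se < 0.05
        assert abs(result.w_z_hat - M1_PARAMS.w_z) < 3.5 * result.se

    def test_likelihood_prefers_truth_over_doubled_noise(self, m1_trials):
        sub = m1_trials[(~m1_trials["sure_shown"]) & (m1_trials["coherence"] != 0)]
        c = sub["coherence"].to_numpy()
        t = sub["duration_steps"].to_numpy(float)
        y = (sub["choice"] == "right").to_numpy()

        def loglik(w):
            p = np.clip(norm.cdf(np.sqrt(t) * c / w), 1e-12, 1 - 1e-12)
            return np.log(p[y]).sum() + np.log1p(-p[~y]).sum()

        assert loglik(0.9) > loglik(1.8)

    def test_chance_level_choices_flagged_at_boundary(self, rng):
        n = 4_000
        trials = pd.DataFrame(
            {
                "coherence": rng.choice([0.128, -0.128], n),
                "duration_steps": np.full(n, 40),
                "sure_shown": np.zeros(n, bool),
                "choice": rng.choice(["left", "right"], n),  # evidence-free
            }
        )
        result = fit_wz(trials)
        assert result.flags  # noise estimate driven to the search limit


class TestEstimatePrior:
    def test_degenerate_single_zero_coherence_design(self, rng):
        n = 50_000
        trials = pd.DataFrame(
            {
                "coherence": np.zeros(n),
                "duration_steps": np.full(n, 40),
                "sure_shown": np.zeros(n, bool),
            }
        )
        mu0, s0 = estimate_prior(trials, 0.9, rng)
        assert mu0 == pytest.approx(0.0, abs=3 * (0.9 / np.sqrt(40)) / np.sqrt(n))
        assert s0 == pytest.approx(0.9 / np.sqrt(40), rel=0.02)

    def test_invariant_to_trial_order_given_draws(self, m1_trials, rng):
        draws = rng.standard_normal(len(m1_trials))
        a = estimate_prior(m1_trials, 0.9, rng, standard_draws=draws)
        perm = rng.permutation(len(m1_trials))
        shuffled = m1_trials.iloc[perm].reset_index(drop=True)
        b = estimate_prior(shuffled, 0.9, rng, standard_draws=draws[perm])
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[1] == pytest.approx(b[1], rel=1e-9)

    def test_width_reflects_coherence_spread_plus_inference_noise(self, m1_trials, rng):
        _, s0 = estimate_prior(m1_trials, 1.6, rng)
        c = m1_trials["coherence"].to_numpy()
        t = m1_trials["duration_steps"].to_numpy(float)
        expected = np.sqrt(c.var() + (1.6**2 / t).mean())
        assert s0 == pytest.approx(expected, rel=0.02)

    def test_moment_method_is_deterministic_and_matches_sampling(self, m1_trials, rng):
        mu_m, s0_m = estimate_prior(m1_trials, 1.6, method="moment")
        assert (mu_m, s0_m) == estimate_prior(m1_trials, 1.6, method="moment")
        _, s0_s = estimate_prior(m1_trials, 1.6, rng)
        assert s0_m == pytest.approx(s0_s, rel=0.02)


class TestFitSigmaZ:
    def test_flat_prior_limit_matches_reduced_oracle(self, m1_trials, rng):
        draws = rng.standard_normal(len(m1_trials))
        result = fit_sigma_z(m1_trials, 0.9, 1e6, rng, standard_draws=draws)

        sub = m1_trials[(~m1_trials["sure_shown"]) & (m1_trials["coherence"] != 0)]
        mask = ((~m1_trials["sure_shown"]) & (m1_trials["coherence"] != 0)).to_numpy()
        c = sub["coherence"].to_numpy()
        t = sub["duration_steps"].to_numpy(float)
        y = (sub["choice"] == "right").to_numpy()
        s = t * c + np.sqrt(t) * 0.9 * draws[mask]

        def oracle_nll(sigma_z):
            # flat-prior reduction: belief = Phi(sum / (sigma_z sqrt(t)))
            p = np.clip(norm.cdf(s / (sigma_z * np.sqrt(t))), 1e-12, 1 - 1e-12)
            return -(np.log(p[y]).sum() + np.log1p(-p[~y]).sum())

        oracle = minimize_scalar(
            oracle_nll, bounds=(0.05, 20), method="bounded", options={"xatol": 1e-6}
        ).x
        assert result.sigma_z_hat == pytest.approx(oracle, rel=1e-3)

    def test_evidence_free_choices_leave_noise_unidentified(self, rng):
        n = 5_000
        trials = pd.DataFrame(
            {
                "coherence": rng.choice([0.128, -0.128], n),
                "duration_steps": np.full(n, 40),
                "sure_shown": np.zeros(n, bool),
                "choice": rng.choice(["left", "right"], n),
            }
        )
        result = fit_sigma_z(trials, 0.9, 0.46, rng)
        assert result.flags  # pushed to a search boundary


class TestIteratePriorNoise:
    def test_converges_quickly_and_faster_at_printed_precision(self, m1_trials):
        # the iteration contracts by roughly x4 per pass; at the default
        # tolerance it settles within 6 passes, and at the two-decimal
        # precision of the reference parameter values within fewer than 5
        result = iterate_prior_noise(m1_trials, 0.9, rng=np.random.default_rng(42))
        assert result.converged
        assert result.n_iterations <= 6
        assert result.sigma_0_hat > 0 and result.sigma_z_hat > 0
        coarse = iterate_prior_noise(
            m1_trials, 0.9, tol=0.01, rng=np.random.default_rng(42)
        )
        assert coarse.converged and coarse.n_iterations < 5

    def test_fixed_point_is_self_consistent(self, m1_trials):
        # at convergence the prior width must equal the spread implied by
        # the final learned noise
        result = iterate_prior_noise(m1_trials, 0.9, rng=np.random.default_rng(43))
        rng_check = np.random.default_rng(44)
        _, s0 = estimate_prior(m1_trials, result.sigma_z_hat, rng_check)
        assert result.sigma_0_hat == pytest.approx(s0, rel=0.02)

    def test_deterministic_given_generator_seed(self, m1_trials):
        a = iterate_prior_noise(m1_trials, 0.9, rng=np.random.default_rng(45))
        b = iterate_prior_noise(m1_trials, 0.9, rng=np.random.default_rng(45))
        assert a.sigma_0_hat == b.sigma_0_hat
        assert a.sigma_z_hat == b.sigma_z_hat


class TestFitUtilityRatio:
    def test_recovers_generating_threshold_within_two_hundredths(self, m1_trials):
        result = fit_utility_ratio(m1_trials, M1_PARAMS)
        assert result.utility_ratio_hat == pytest.approx(
            M1_PARAMS.utility_ratio, abs=0.02
        )

    def test_optout_probability_decreases_with_strength_and_duration(self):
        p_by_c = [
            surebet_prob_zero_cost(c, 40, 0.63, M1_PARAMS) for c in (0.0, 0.064, 0.256)
        ]
        assert p_by_c[0] > p_by_c[1] > p_by_c[2]
        p_by_t = [
            surebet_prob_zero_cost(0.064, t, 0.63, M1_PARAMS) for t in (10, 40, 90)
        ]
        assert p_by_t[0] > p_by_t[1] > p_by_t[2]

    def test_indifferent_threshold_never_chooses_sure(self, m1_trials):
        # confidence is always >= 1/2, so as the ratio approaches 1/2 the
        # opt-out probability vanishes continuously
        p = surebet_prob_zero_cost(0.064, 40, 0.501, M1_PARAMS)
        assert p < 0.005
        assert surebet_prob_zero_cost(0.064, 40, 0.5001, M1_PARAMS) < p

    def test_requires_sure_trials(self, m1_trials):
        with pytest.raises(ValueError):
            fit_utility_ratio(m1_trials[~m1_trials["sure_shown"]], M1_PARAMS)


class TestParticleFilter:
    def test_matches_closed_form_likelihood_without_cost(self, rng):
        trials = generate_trials(TaskConfig(n_trials=2_000, seed=46))
        sim = simulate_fixed_duration(trials, M1_PARAMS, rng=np.random.default_rng(46))
        sub = sim[(~sim["sure_shown"]) & (sim["coherence"] != 0)]
        c = sub["coherence"].to_numpy()
        t = sub["duration_steps"].to_numpy(float)
        y = (sub["choice"] == "right").to_numpy()
        p = np.clip(norm.cdf(np.sqrt(t) * c / M1_PARAMS.w_z), 1e-4, 1 - 1e-4)
        closed = np.log(p[y]).sum() + np.log1p(-p[~y]).sum()
        pf = particle_filter_loglik(sim, M1_PARAMS, n_particles=20_000, rng=rng)
        assert pf == pytest.approx(closed, abs=0.02 * abs(closed))

    def test_estimate_spread_shrinks_with_more_particles(self):
        trials = generate_trials(TaskConfig(n_trials=300, seed=47))
        sim = simulate_fixed_duration(trials, M1_PARAMS, rng=np.random.default_rng(47))
        params = M1_PARAMS.with_(cost=1e-4)

        def spread(n_particles):
            vals = [
                particle_filter_loglik(
                    sim, params, n_particles=n_particles, rng=np.random.default_rng(k)
                )
                for k in range(8)
            ]
            return np.var(vals)

        assert spread(2_000) < spread(200)


class TestGridSearchCostModel:
    def test_zero_cost_data_puts_maximum_at_zero_cost_and_true_wz(self):
        trials = generate_trials(TaskConfig(n_trials=4_000, seed=48))
        sim = simulate_fixed_duration(trials, M1_PARAMS, rng=np.random.default_rng(48))
        result = grid_search_cost_model(
            sim,
            cost_grid=np.array([0.0, 2e-4, 5e-4]),
            wz_grid=np.array([0.8, 0.9, 1.0]),
            n_particles=4_000,
            rng=np.random.default_rng(49),
        )
        assert result.cost_hat <= 2e-4  # truth on the grid boundary
        assert result.w_z_hat == pytest.approx(0.9, abs=0.1)
        assert len(result.surface) == 9
        assert result.surface["loglik"].max() == result.loglik


class TestVuong:
    def test_hand_computed_five_point_example(self):
        # worked by hand: sum = 0.3, penalty = 0.5*ln 5, w = rms = 0.18166
        llr = np.array([0.2, -0.1, 0.05, 0.3, -0.15])
        z, p = vuong_test(llr, k1=2, k2=1, penalized=True)
        assert z == pytest.approx(-1.2424, abs=2e-4)
        assert p == pytest.approx(0.2141, abs=2e-4)
        z_plain, _ = vuong_test(llr, penalized=False)
        assert z_plain == pytest.approx(0.3 / (np.sqrt(5) * 0.181659), abs=2e-4)

    def test_identical_models_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            vuong_test(np.zeros(10))

    def test_matched_likelihoods_give_small_statistic(self, rng):
        llr = rng.normal(0.0, 0.3, 500)
        llr -= llr.mean()  # L1 == L2 but pointwise terms differ
        z, p = vuong_test(llr, k1=3, k2=3, centered=True)
        assert abs(z) < 0.5

    def test_null_calibration_rarely_rejects(self, rng):
        rejections = 0
        for _ in range(40):
            llr = rng.normal(0.0, 0.2, 1_000)  # equally close models
            _, p = vuong_test(llr)
            rejections += p < 0.05
        assert rejections <= 6
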