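"""Adaptive staircase: Bayesian bookkeeping and convergence to the
75%-correct threshold."""

import numpy as np
import pytest

from expectprofile.observer import ObserverSpec, flat_profile, p_correct_2afc
from expectprofile.quest import (quest_create, quest_update,
                                 quest_next_intensity, quest_final_estimate,
                                 quest_mean_db, p_correct_given_threshold,
                                 run_staircase, to_db, from_db)


def small_state(halfwidth=1.0, grain=1.0, **kw):
    # grid at {-h, ..., +h} around 0 dB (threshold 1.0 stimulus units)
    return quest_create(0.0, prior_sd_db=5.0, grid_halfwidth=halfwidth,
                        grain=grain, **kw)


class TestPosterior:
    def test_prior_is_normalized_gaussian_peaked_at_mean(self):
        s = quest_create(2.0, 1.5, grid_halfwidth=10, grain=0.05)
        assert s.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert s.grid_db[np.argmax(s.posterior)] == pytest.approx(2.0, abs=0.05)

    def test_wider_prior_has_higher_entropy(self):
        ent = lambda p: -np.sum(p * np.log(np.maximum(p, 1e-300)))
        narrow = quest_create(0.0, 1.0)
        wide = quest_create(0.0, 5.0)
        assert ent(wide.posterior) > ent(narrow.posterior)

    def test_update_matches_brute_force_bayes_on_three_point_grid(self):
        """Posterior after one trial equals prior x likelihood / evidence,
        with the likelihood written out longhand."""
        s = small_state(halfwidth=1.0, grain=1.0, beta=3.5, guess=0.5,
                        lapse=0.01, target_p=0.75)
        prior = s.posterior.copy()
        intensity = 1.2
        quest_update(s, intensity, True)
        # longhand likelihood at each candidate threshold
        c = -np.log1p(-(0.75 - 0.5) / (1 - 0.5 - 0.01))
        lik = []
        for t_db in (-1.0, 0.0, 1.0):
            r = 10 ** ((20 * np.log10(intensity) - t_db) / 20)
            w = 1 - np.exp(-c * r ** 3.5)
            lik.append(0.5 + (1 - 0.5 - 0.01) * w)
        expected = prior * np.array(lik)
        expected /= expected.sum()
        assert np.allclose(s.posterior, expected, atol=1e-14)

    def test_normalization_preserved_over_many_updates(self, rng):
        s = quest_create(0.0, 3.0)
        for _ in range(200):
            quest_update(s, float(from_db(rng.uniform(-5, 5))),
                         bool(rng.random() < 0.7))
        assert abs(s.posterior.sum() - 1.0) < 1e-12

    def test_incorrect_at_low_intensity_raises_posterior_mean(self):
        s = quest_create(0.0, 3.0)
        before = quest_mean_db(s)
        quest_update(s, float(from_db(-6.0)), False)
        assert quest_mean_db(s) > before

    def test_flat_likelihood_pair_is_identity(self):
        # a correct and an incorrect pseudo-update with p = 0.5 everywhere
        # (guess-rate floor at zero intensity ratio) leave the posterior alone
        s = quest_create(0.0, 3.0)
        p = p_correct_given_threshold(-200.0, s.grid_db, 3.5, 0.5, 0.01, 0.75)
        assert np.allclose(p, 0.5, atol=1e-12)

    def test_nonboolean_response_rejected(self):
        s = quest_create(0.0, 3.0)
        with pytest.raises(TypeError):
            quest_update(s, 1.0, 1)


class TestPlacementAndEstimate:
    def test_symmetric_posterior_recommends_grid_center(self):
        s = quest_create(0.0, 2.0)
        assert quest_next_intensity(s) == pytest.approx(1.0)  # 0 dB

    def test_placement_is_posterior_mean_dot_product(self, rng):
        s = quest_create(0.0, 2.0, grid_halfwidth=2.0, grain=1.0)  # 5 points
        s.posterior = rng.dirichlet(np.ones(5))
        assert quest_next_intensity(s) == pytest.approx(
            float(from_db(np.dot(s.posterior, s.grid_db))))

    def test_repeated_correct_responses_lower_recommendation(self):
        s = quest_create(0.0, 3.0)
        recs = []
        for _ in range(10):
            x = quest_next_intensity(s)
            recs.append(x)
            quest_update(s, x, True)
        assert all(b < a + 1e-12 for a, b in zip(recs, recs[1:]))

    def test_estimate_requires_history(self):
        with pytest.raises(ValueError, match="undefined"):
            quest_final_estimate(quest_create(0.0, 2.0))


class TestConvergence:
    def test_estimates_unbiased_at_known_threshold(self):
        """40-trial staircases against a true 2.0-deg threshold recover it
        on average (500 replicates, 3 standard errors)."""
        obs = ObserverSpec(baseline_dt_od=2.0, ds_profile=flat_profile())
        rng = np.random.default_rng(1)
        ests = np.array([run_staircase(obs, "OD", "baseline", 0.0, 40, rng)
                         for _ in range(500)])
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 2.0) < 3 * se + 0.02

    def test_percent_correct_at_estimate_matches_criterion(self):
        """Probing the observer at the returned estimates yields ~75%
        correct: the staircase estimates the 75%-correct threshold."""
        obs = ObserverSpec(baseline_dt_od=2.0, ds_profile=flat_profile())
        rng = np.random.default_rng(2)
        pcs = []
        for _ in range(100):
            est = run_staircase(obs, "OD", "baseline", 0.0, 40, rng)
            pcs.append(p_correct_2afc(est, dt=2.0))
        assert np.mean(pcs) == pytest.approx(0.75, abs=0.02)

    def test_rmse_decreases_with_trial_count(self):
        obs = ObserverSpec(baseline_dt_od=2.0, ds_profile=flat_profile())
        rng = np.random.default_rng(3)
        rmse = []
        for n in (10, 20, 40, 80):
            ests = np.array([run_staircase(obs, "OD", "baseline", 0.0, n, rng)
                             for _ in range(120)])
            rmse.append(np.sqrt(np.mean((ests - 2.0) ** 2)))
        assert rmse[0] > rmse[1] > rmse[2] > rmse[3]

    def test_step_observer_limit(self):
        """With lapse 0 and a near-step psychometric the estimate converges
        to the step location."""
        obs = ObserverSpec(baseline_dt_od=2.0, ds_profile=flat_profile(),
                           weibull_beta=40.0, lapse=0.0)
        rng = np.random.default_rng(4)
        ests = [run_staircase(obs, "OD", "baseline", 0.0, 80, rng)
                for _ in range(20)]
        assert np.mean(ests) == pytest.approx(2.0, rel=0.1)


def test_db_conversions_roundtrip():
    x = np.array([0.05, 1.0, 3.7])
    assert np.allclose(from_db(to_db(x)), x)
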