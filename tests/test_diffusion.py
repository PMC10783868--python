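"""Forward/posterior distributional checks for both chains."""

import numpy as np
import pytest
from scipy import stats

from pocketdiff.diffusion import (
    DiffusionState,
    NoiseSchedule,
    forward_coords,
    forward_types,
    kl_categorical,
    posterior_coords,
    posterior_types,
)


@pytest.fixture(scope="module")
def sched():
    return NoiseSchedule.create(T=100)


class TestSchedule:
    def test_cumulative_products_agree_with_incremental(self, sched):
        inc = 1.0
        for t in range(1, sched.T + 1):
            inc *= 1.0 - sched.beta_at(t)
            assert abs(inc - sched.alpha_bar_at(t)) < 1e-12

    def test_terminal_state_is_nearly_pure_noise(self, sched):
        assert sched.alpha_bar_at(sched.T) < 0.01

    def test_alpha_bar_strictly_decreasing(self, sched):
        ab = sched.alpha_bar
        assert (np.diff(ab) < 0).all()

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            NoiseSchedule(T=3, beta=np.array([0.5, 0.2, 0.9]),
                          cat_alpha=np.ones(3) * 0.9)


class TestForwardCoords:
    def test_zero_noise_limit_returns_input(self):
        sched = NoiseSchedule(T=2, beta=np.array([1e-12, 1e-12]),
                              cat_alpha=np.array([1.0, 1.0]))
        x0 = np.ones((4, 3))
        out = forward_coords(x0, 1, sched, np.random.default_rng(0))
        assert np.allclose(out, x0, atol=1e-5)

    def test_terminal_moments_match_closed_form(self, sched):
        rng = np.random.default_rng(5)
        x0 = np.array([[2.0, -1.0, 0.5]])
        n = 10_000
        draws = np.array([forward_coords(x0, sched.T, sched, rng)[0]
                          for _ in range(n)])
        ab = sched.alpha_bar_at(sched.T)
        se = np.sqrt((1 - ab) / n)
        assert np.all(np.abs(draws.mean(axis=0) - np.sqrt(ab) * x0[0]) < 4 * se)

    def test_two_step_composition_matches_direct_marginal(self, sched):
        # q(x_t | x_s) composed with q(x_s | x_0) must match q(x_t | x_0)
        rng = np.random.default_rng(6)
        x0 = np.array([[1.0, 2.0, 3.0]])
        s, t = 40, 80
        ab_s, ab_t = sched.alpha_bar_at(s), sched.alpha_bar_at(t)
        ratio = ab_t / ab_s
        n = 10_000
        comp = np.empty((n, 3))
        for i in range(n):
            xs = forward_coords(x0, s, sched, rng)
            comp[i] = (np.sqrt(ratio) * xs
                       + np.sqrt(1 - ratio) * rng.standard_normal(3))
        se_mean = np.sqrt((1 - ab_t) / n)
        assert np.all(np.abs(comp.mean(axis=0) - np.sqrt(ab_t) * x0[0])
                      < 4 * se_mean)
        var = comp.var(axis=0)
        se_var = (1 - ab_t) * np.sqrt(2.0 / n)
        assert np.all(np.abs(var - (1 - ab_t)) < 4 * se_var)

    def test_prior_convergence_kolmogorov_smirnov(self, sched):
        rng = np.random.default_rng(7)
        x0 = np.zeros((1, 3))
        draws = np.array([forward_coords(x0, sched.T, sched, rng).ravel()
                          for _ in range(4000)]).ravel()
        ab = sched.alpha_bar_at(sched.T)
        stat = stats.kstest(draws / np.sqrt(1 - ab), "norm")
        assert stat.pvalue > 0.01

    def test_reproducible_given_seed(self, sched):
        x0 = np.ones((3, 3))
        a = forward_coords(x0, 50, sched, np.random.default_rng(9))
        b = forward_coords(x0, 50, sched, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_t_out_of_range(self, sched):
        with pytest.raises(ValueError):
            forward_coords(np.zeros((1, 3)), sched.T + 1, sched,
                           np.random.default_rng(0))


class TestForwardTypes:
    def test_identity_transition_keeps_labels(self):
        sched = NoiseSchedule(T=2, beta=np.array([1e-4, 1e-4]),
                              cat_alpha=np.array([1.0, 1.0]))
        z0 = np.eye(4)[:, :4]
        out = forward_types(z0, 2, sched, np.random.default_rng(0))
        assert np.array_equal(out, z0)

    def test_full_noise_gives_uniform_frequencies(self):
        K = 4
        sched = NoiseSchedule(T=1, beta=np.array([0.5]),
                              cat_alpha=np.array([1e-9]))
        z0 = np.tile(np.eye(K)[0], (10_000, 1))
        out = forward_types(z0, 1, sched, np.random.default_rng(1))
        freqs = out.mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(freqs - 1 / K) < 4 * se)

    def test_midchain_transition_matches_analytic(self):
        K = 2
        sched = NoiseSchedule.create(T=10)
        t = 5
        ab = sched.cat_alpha_bar_at(t)
        z0 = np.tile([1.0, 0.0], (10_000, 1))
        out = forward_types(z0, t, sched, np.random.default_rng(2))
        p_keep = ab + (1 - ab) / K
        se = np.sqrt(p_keep * (1 - p_keep) / 10_000)
        assert abs(out[:, 0].mean() - p_keep) < 4 * se

    def test_rejects_non_one_hot(self):
        sched = NoiseSchedule.create(T=10)
        with pytest.raises(ValueError):
            forward_types(np.array([[0.5, 0.5]]), 1, sched,
                          np.random.default_rng(0))


class TestPosteriorCoords:
    def test_t1_collapses_to_prediction(self, sched):
        x_t = np.random.default_rng(0).standard_normal((2, 3))
        x0_hat = np.random.default_rng(1).standard_normal((2, 3))
        mu, beta_tilde = posterior_coords(x_t, x0_hat, 1, sched)
        assert np.allclose(mu, x0_hat, atol=1e-9)
        assert beta_tilde == pytest.approx(0.0, abs=1e-15)

    def test_matches_independent_formula(self, sched):
        rng = np.random.default_rng(3)
        x_t, x0_hat = rng.standard_normal((2, 5, 3))
        t = 37
        mu, beta_tilde = posterior_coords(x_t, x0_hat, t, sched)
        # duplicate evaluation, written out long-hand
        b = sched.beta_at(t)
        abt, abp = sched.alpha_bar_at(t), sched.alpha_bar_at(t - 1)
        mu2 = (np.sqrt(abp) * b * x0_hat
               + np.sqrt(1 - b) * (1 - abp) * x_t) / (1 - abt)
        assert np.allclose(mu, mu2, atol=1e-12)
        assert beta_tilde == pytest.approx((1 - abp) * b / (1 - abt))

    def test_rejects_t_zero(self, sched):
        with pytest.raises(ValueError):
            posterior_coords(np.zeros((1, 3)), np.zeros((1, 3)), 0, sched)


class TestPosteriorTypes:
    def test_identity_chain_returns_clean_distribution(self):
        sched = NoiseSchedule(T=3, beta=np.full(3, 1e-4),
                              cat_alpha=np.ones(3))
        z = np.array([1.0, 0.0, 0.0])
        post = posterior_types(z, z, 2, sched)
        assert np.allclose(post, z)

    def test_uniform_everything_stays_uniform(self):
        sched = NoiseSchedule(T=3, beta=np.full(3, 1e-4),
                              cat_alpha=np.full(3, 0.5))
        K = 4
        z_t = np.full(K, 1.0)
        z0 = np.full(K, 1.0 / K)
        post = posterior_types(z_t, z0, 2, sched)
        assert np.allclose(post, 1.0 / K, atol=1e-12)

    def test_two_class_chain_matches_exhaustive_enumeration(self):
        sched = NoiseSchedule.create(T=6)
        K, t = 2, 3
        a_t = sched.cat_alpha_at(t)
        ab_prev = sched.cat_alpha_bar_at(t - 1)
        z0 = np.array([0.7, 0.3])
        z_t = np.array([0.0, 1.0])
        # enumerate z_{t-1} candidates explicitly
        expected = np.empty(K)
        for j in range(K):
            lik = a_t * z_t[j] + (1 - a_t) / K
            prior = ab_prev * z0[j] + (1 - ab_prev) / K
            expected[j] = lik * prior
        expected /= expected.sum()
        post = posterior_types(z_t, z0, t, sched)
        assert np.allclose(post, expected, atol=1e-10)

    def test_rows_sum_to_one(self, sched):
        rng = np.random.default_rng(4)
        z_t = rng.random((6, 8)) + 0.01
        z0 = rng.random((6, 8)) + 0.01
        post = posterior_types(z_t, z0, 50, sched)
        assert np.allclose(post.sum(axis=-1), 1.0, atol=1e-12)

    def test_rejects_zero_mass_z0(self, sched):
        with pytest.raises(ValueError):
            posterior_types(np.array([1.0, 0.0]), np.zeros(2), 5, sched)


class TestKL:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_categorical(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_closed_form_log2(self):
        assert kl_categorical(np.array([1.0, 0.0]), np.array([0.5, 0.5])) \
            == pytest.approx(np.log(2))

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(5); p /= p.sum()
            q = rng.random(5); q /= q.sum()
            assert kl_categorical(p, q) >= 0.0
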