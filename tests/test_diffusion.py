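"""Schedule, forward/reverse kernels, posterior and loss of the diffusion core."""

import numpy as np
import pytest

from longidiff.diffusion import (ConditionSet, NoisyState, estimate_x0,
                                 forward_sample, forward_step, make_schedule,
                                 posterior_params)


class TestSchedule:
    def test_single_step_product(self):
        s = make_schedule(1, 0.1, 0.1)
        assert s.alpha_bar == pytest.approx([0.9])

    def test_two_step_hand_product(self):
        s = make_schedule(2, 0.1, 0.2)
        assert s.alpha_bar == pytest.approx([0.9, 0.72])

    def test_default_schedule_reaches_pure_noise(self):
        s = make_schedule(1000, 1e-4, 0.02)
        assert s.alpha_bar[-1] < 1e-4
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert np.allclose(s.alpha_bar, np.cumprod(s.alpha))

    def test_posterior_variance_convention(self):
        s = make_schedule(10, 1e-3, 0.1)
        assert s.posterior_var[0] == 0.0  # abar_0 := 1
        assert np.all(s.posterior_var >= 0)
        assert np.all(s.posterior_var <= s.beta + 1e-15)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(T=0), "T"),
        (dict(T=5, beta_start=0.0), "beta_start"),
        (dict(T=5, beta_start=0.2, beta_end=0.1), "beta_start"),
        (dict(T=5, beta_end=1.0), "beta"),
    ])
    def test_invalid_inputs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            make_schedule(**{"beta_start": 1e-4, "beta_end": 0.02, **kwargs})


class TestForwardProcess:
    sched = make_schedule(2, 0.1, 0.2)

    def test_zero_noise_scales_signal(self):
        x0 = np.full((3, 3), 2.0)
        out = forward_sample(x0, 2, np.zeros((3, 3)), self.sched)
        assert np.allclose(out.x_t, np.sqrt(0.72) * 2.0)

    def test_zero_signal_scales_noise(self):
        eps = np.ones((2, 2))
        out = forward_sample(np.zeros((2, 2)), 1, eps, self.sched)
        assert np.allclose(out.x_t, np.sqrt(0.1))

    def test_scalar_closed_form(self):
        out = forward_sample(np.array(1.0), 2, np.array(1.0), self.sched)
        assert out.x_t == pytest.approx(np.sqrt(0.72) + np.sqrt(0.28), abs=1e-5)
        assert out.x_t == pytest.approx(1.37776, abs=1e-4)

    def test_forward_step_arithmetic(self):
        s = make_schedule(1, 0.19, 0.19)
        out = forward_step(np.array(2.0), 1, np.array(0.0), s)
        assert out.x_t == pytest.approx(np.sqrt(0.81) * 2.0)
        assert out.x_t == pytest.approx(1.8)

    def test_tiny_beta_is_near_identity(self):
        s = make_schedule(1, 1e-12, 1e-12)
        out = forward_step(np.array(3.0), 1, np.array(5.0), s)
        assert out.x_t == pytest.approx(3.0, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            forward_sample(np.zeros(3), 1, np.zeros(4), self.sched)
        with pytest.raises(ValueError, match="t="):
            forward_sample(np.zeros(3), 3, np.zeros(3), self.sched)

    def test_iterated_steps_match_closed_form_moments(self):
        """Monte Carlo: t iterated single-step kernels reproduce the
        closed-form q(x_t | x_0) moments within 3 standard errors."""
        sched = make_schedule(50, 2e-3, 0.05)
        rng = np.random.default_rng(0)
        n = 100_000
        x = np.full(n, 1.0)
        for t in range(1, sched.T + 1):
            x = forward_step(x, t, rng.standard_normal(n), sched).x_t
        ab = sched.abar(sched.T)
        exp_mean, exp_var = np.sqrt(ab) * 1.0, 1.0 - ab
        se_mean = np.sqrt(exp_var / n)
        se_var = exp_var * np.sqrt(2.0 / (n - 1))
        assert abs(x.mean() - exp_mean) < 3 * se_mean
        assert abs(x.var() - exp_var) < 3 * se_var


class TestEstimateX0:
    def test_inversion_of_forward_sample(self):
        sched = make_schedule(40, 1e-3, 0.3)
        rng = np.random.default_rng(1)
        for _ in range(1000):
            t = int(rng.integers(1, sched.T + 1))
            x0 = rng.standard_normal(4)
            eps = rng.standard_normal(4)
            xt = forward_sample(x0, t, eps, sched).x_t
            rec = estimate_x0(xt, t, eps, sched)
            assert np.max(np.abs(rec - x0)) < 1e-6 * max(1.0, np.max(np.abs(x0)))

    def test_zero_eps_rescales(self):
        sched = make_schedule(2, 0.1, 0.2)
        xt = np.array([1.0, 2.0])
        assert np.allclose(estimate_x0(xt, 2, np.zeros(2), sched),
                           xt / np.sqrt(0.72))

    def test_worked_scalar_example(self):
        sched = make_schedule(2, 0.1, 0.2)
        xt = np.sqrt(0.72) + np.sqrt(0.28)
        assert estimate_x0(np.array(xt), 2, np.array(1.0), sched) == \
            pytest.approx(1.0)


def _conjugate_posterior(x_t, x0, t, sched):
    """Independent oracle: exact Bayes posterior q(x_{t-1} | x_t, x_0) from
    the two Gaussian kernels, via scalar precision-weighted combination."""
    ab_prev = 1.0 if t == 1 else sched.alpha_bar[t - 2]
    alpha_t = sched.alpha[t - 1]
    beta_t = sched.beta[t - 1]
    # prior: x_{t-1} | x0 ~ N(sqrt(ab_prev) x0, 1 - ab_prev)
    # likelihood: x_t | x_{t-1} ~ N(sqrt(alpha_t) x_{t-1}, beta_t)
    prior_var = 1.0 - ab_prev
    if prior_var == 0.0:
        return np.sqrt(ab_prev) * x0, 0.0
    prec = 1.0 / prior_var + alpha_t / beta_t
    var = 1.0 / prec
    mean = var * (np.sqrt(ab_prev) * x0 / prior_var
                  + np.sqrt(alpha_t) * x_t / beta_t)
    return mean, var


class TestPosterior:
    sched = make_schedule(12, 5e-3, 0.25)

    def test_matches_conjugate_gaussian_oracle(self):
        """Grid of (x_t, x0_hat, t): closed-form coefficients equal the
        brute-force conjugate-Bayes posterior to 1e-8 relative error."""
        for t in range(1, self.sched.T + 1):
            ab = self.sched.abar(t)
            for x_t in np.linspace(-2, 2, 5):
                for x0 in np.linspace(-1.5, 1.5, 5):
                    # eps consistent with (x_t, x0)
                    eps = (x_t - np.sqrt(ab) * x0) / np.sqrt(1 - ab)
                    mean, var = posterior_params(np.array(x_t), t,
                                                 np.array(eps), self.sched)
                    omean, ovar = _conjugate_posterior(x_t, x0, t, self.sched)
                    assert abs(mean - omean) <= 1e-8 * max(1.0, abs(omean))
                    assert abs(var - ovar) <= 1e-8 * max(1.0, abs(ovar))

    def test_final_step_collapses_to_x0_estimate(self):
        x_t = np.array([0.4, -0.2])
        eps = np.array([0.1, 0.3])
        mean, var = posterior_params(x_t, 1, eps, self.sched)
        assert var == 0.0
        assert np.allclose(mean, estimate_x0(x_t, 1, eps, self.sched))

    def test_true_eps_equals_true_x0_form(self):
        rng = np.random.default_rng(3)
        x0 = rng.standard_normal(5)
        eps = rng.standard_normal(5)
        t = 7
        x_t = forward_sample(x0, t, eps, self.sched).x_t
        mean, _ = posterior_params(x_t, t, eps, self.sched)
        omean = np.array([_conjugate_posterior(x_t[i], x0[i], t, self.sched)[0]
                          for i in range(5)])
        assert np.allclose(mean, omean)

    def test_x0_clipping_applies(self):
        mean_c, _ = posterior_params(np.array(50.0), 5, np.array(0.0),
                                     self.sched, clip_x0=(0.0, 1.0))
        mean_u, _ = posterior_params(np.array(50.0), 5, np.array(0.0),
                                     self.sched)
        assert mean_c < mean_u


class TestTypes:
    def test_noisy_state_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            NoisyState(np.array([np.nan]), 1)

    def test_condition_set_arity(self):
        img = np.zeros((4, 4, 4))
        assert ConditionSet("P", (img,)).n_images == 1
        assert ConditionSet("PF", (img, img)).n_images == 2
        with pytest.raises(ValueError, match="requires 1"):
            ConditionSet("P", (img, img))
        with pytest.raises(ValueError, match="requires 2"):
            ConditionSet("PF", (img,))
        with pytest.raises(ValueError, match="shape"):
            ConditionSet("PF", (img, np.zeros((4, 4, 5))))
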