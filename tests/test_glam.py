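import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from valconf.glam import (GLAMModel, GLAMParams, drift_terms, race_density,
                          simulate_trial, simulate_trials, wald_cdf,
                          wald_logsf, wald_pdf)


class TestDriftTerms:
    def test_equal_signals_give_half(self, base_params):
        r_i, r_j = drift_terms(0.6, 0.6, 0.5, base_params)
        assert r_i == pytest.approx(0.5) and r_j == pytest.approx(0.5)

    def test_full_effort_ignores_gaze(self, base_params):
        p = base_params.replace(theta=1.0)
        for g in (0.1, 0.5, 0.9):
            r_i, _ = drift_terms(0.7, 0.4, g, p)
            assert r_i == pytest.approx(drift_terms(0.7, 0.4, 0.5, p)[0])

    def test_zero_effort_full_gaze_drops_unattended(self, base_params):
        # theta = 0, g_i = 1: S_i = v_i, S_j = 0
        p = base_params.replace(theta=0.0)
        r_i, _ = drift_terms(0.7, 0.4, 1.0, p)
        expected = 1.0 / (1.0 + np.exp(-p.tau * 0.7))
        assert r_i == pytest.approx(expected)

    def test_value_tau_rescaling_invariance(self, base_params, rng):
        # multiplying values by alpha and dividing tau by alpha leaves R fixed
        alpha = 3.7
        v_i, v_j, g = rng.random(20), rng.random(20), rng.random(20)
        r1, _ = drift_terms(v_i, v_j, g, base_params)
        r2, _ = drift_terms(alpha * v_i, alpha * v_j, g,
                            base_params.replace(tau=base_params.tau / alpha))
        np.testing.assert_allclose(r1, r2, rtol=1e-12)


class TestWald:
    def test_matches_scipy_inverse_gaussian(self):
        B, k, R, sigma = 1.0, 1.5, 0.6, 0.4
        mu, lam = B / (k * R), B * B / sigma ** 2
        t = np.linspace(0.05, 8, 50)
        ref = stats.invgauss.pdf(t, mu / lam, scale=lam)
        np.testing.assert_allclose(wald_pdf(t, B, k, R, sigma), ref,
                                   rtol=1e-10)
        ref_cdf = stats.invgauss.cdf(t, mu / lam, scale=lam)
        np.testing.assert_allclose(wald_cdf(t, B, k, R, sigma), ref_cdf,
                                   rtol=1e-8, atol=1e-12)

    def test_density_integrates_to_one(self):
        val, _ = quad(lambda t: wald_pdf(t, 1, 1, 0.5, 1), 0, np.inf,
                      limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_closed_form(self):
        B, k, R, sigma = 1.0, 2.0, 0.7, 0.5
        mu, lam = B / (k * R), B * B / sigma ** 2
        mode = mu * (np.sqrt(1 + 9 * mu ** 2 / (4 * lam ** 2))
                     - 3 * mu / (2 * lam))
        t = np.linspace(1e-3, 3, 100_000)
        t_argmax = t[np.argmax(wald_pdf(t, B, k, R, sigma))]
        assert t_argmax == pytest.approx(mode, abs=1e-3)

    def test_doubling_bound_quadruples_shape(self):
        # lambda = B^2 / sigma^2; read off through the pdf at matched mu
        t = 0.8
        f1 = wald_pdf(t, 1.0, 1.0, 0.5, 1.0)
        f2 = wald_pdf(t, 2.0, 2.0, 0.5, 1.0)   # same mu, lambda x4
        lam1, lam4 = 1.0, 4.0
        mu = 2.0
        expect_ratio = (np.sqrt(lam4 / lam1)
                        * np.exp(-(lam4 - lam1) * (t - mu) ** 2
                                 / (2 * mu ** 2 * t)))
        assert f2 / f1 == pytest.approx(expect_ratio, rel=1e-10)

    def test_cdf_zero_at_origin_and_one_at_infinity(self):
        assert wald_cdf(1e-12, 1, 1, 0.5, 1) == pytest.approx(0.0, abs=1e-12)
        assert wald_cdf(1e4, 1, 1, 0.5, 1) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k", [0.05, 0.5, 5.0, 50.0])
    @pytest.mark.parametrize("sigma", [0.05, 0.5, 5.0])
    def test_finite_and_nonnegative_over_wide_ranges(self, k, sigma):
        t = np.logspace(-4, 2, 40)
        f = wald_pdf(t, 1.0, k, 0.5, sigma)
        F = wald_cdf(t, 1.0, k, 0.5, sigma)
        sf = wald_logsf(t, 1.0, k, 0.5, sigma)
        assert np.all(np.isfinite(f)) and np.all(f >= 0)
        assert np.all((F >= 0) & (F <= 1)) and np.all(sf <= 1e-12)


class TestRaceDensity:
    def test_symmetric_trial(self, base_params):
        t = np.linspace(0.1, 3, 20)
        up = race_density(t, "upper", 0.6, 0.6, 0.5, base_params)
        low = race_density(t, "lower", 0.6, 0.6, 0.5, base_params)
        np.testing.assert_allclose(up, low, rtol=1e-12)

    def test_completeness(self, base_params):
        total = sum(
            quad(lambda t: race_density(t, w, 0.7, 0.5, 0.6, base_params),
                 0, np.inf, limit=200)[0] for w in ("upper", "lower"))
        assert total == pytest.approx(1.0, abs=1e-4)


class TestSimulator:
    def test_noiseless_limit(self):
        p = GLAMParams(k=2.0, sigma=1e-6, tau=8.0, theta=0.6)
        out = simulate_trial(0.8, 0.3, 0.6, p, dt=0.0005, seed=0)
        r_up, _ = drift_terms(0.8, 0.3, 0.6, p)
        assert out.winner == "upper"
        assert out.rt_s == pytest.approx(p.B / (p.k * r_up), rel=2e-3)

    def test_loser_always_below_bound(self, base_params, rng):
        out = simulate_trials(np.full(500, 0.7), np.full(500, 0.5),
                              rng.random(500), base_params, dt=0.002, rng=1)
        assert np.all(out["loser_evidence"] < base_params.B)

    def test_choice_probability_matches_analytic(self, base_params):
        n = 20_000
        out = simulate_trials(np.full(n, 0.7), np.full(n, 0.55),
                              np.full(n, 0.6), base_params, dt=0.001, rng=7)
        analytic, _ = quad(
            lambda t: race_density(t, "upper", 0.7, 0.55, 0.6, base_params),
            0, np.inf, limit=200)
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(out["choice_upper"].mean() - analytic) < 3 * se

    def test_convergence_with_shrinking_step(self, base_params):
        # simulated choice probability approaches the analytic value as
        # the Euler step shrinks
        analytic, _ = quad(
            lambda t: race_density(t, "upper", 0.8, 0.5, 0.7, base_params),
            0, np.inf, limit=200)
        errs = []
        for dt in (0.01, 0.002, 0.0005):
            out = simulate_trials(np.full(30_000, 0.8), np.full(30_000, 0.5),
                                  np.full(30_000, 0.7), base_params, dt=dt,
                                  rng=11)
            errs.append(abs(out["choice_upper"].mean() - analytic))
        assert errs[-1] <= errs[0] + 0.01


class TestFit:
    def test_recovery_and_theta_self_consistency(self, base_params, rng):
        n = 300
        v_up = rng.uniform(0.2, 0.9, n)
        v_low = np.clip(v_up - rng.choice([0.05, 0.1, 0.15, 0.2], n)
                        * rng.choice([-1, 1], n), 0.05, 0.95)
        g = rng.beta(1.3, 1.3, n)
        p = base_params.replace(theta=1.0)
        out = simulate_trials(v_up, v_low, g, p, dt=0.002, rng=3)
        res = GLAMModel(out["rt_s"], out["choice_upper"], v_up, v_low,
                        g).fit(seed=0)
        assert res.params.k == pytest.approx(p.k, rel=0.2)
        assert res.params.sigma == pytest.approx(p.sigma, rel=0.2)
        # generator used theta = 1: fitted theta mass near 1
        assert res.params.theta > 0.85

    def test_degenerate_rts_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            GLAMModel(np.ones(60), np.ones(60, bool), np.full(60, 0.6),
                      np.full(60, 0.5), np.full(60, 0.5))
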