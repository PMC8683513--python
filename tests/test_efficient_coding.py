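import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from valconf.efficient_coding import (ECChoiceModel, EncodingModel, GMap,
                                      RatingModel, ec_choice_prob,
                                      encode_moments, rating_likelihood)
from valconf.engine import MCMCConfig
from valconf.rum import attentional_rum_choice_prob


class TestEncodeMoments:
    def test_flat_prior_identity(self):
        mean, var = encode_moments(0.3, 0.1, (1.0, 1.0))
        assert mean == pytest.approx(0.3, abs=1e-12)
        assert var == pytest.approx(0.01, abs=1e-15)

    def test_symmetric_prior_center_unbiased(self):
        # Beta(2,2): p'(0.5) = 0 so the decoded mean is exactly v0
        mean, _ = encode_moments(0.5, 0.08, (2.0, 2.0))
        assert mean == pytest.approx(0.5, abs=1e-12)

    def test_monte_carlo_adjudicates_bias_variants(self, rng):
        # simulate the generative chain u = F(v0) + noise, decode phi(u);
        # the half-factor (second-order delta method) variant matches the
        # simulated mean, the as-printed variant overshoots the bias
        a, b, v0, s = 2.0, 5.0, 0.3, 0.06
        u = stats.beta.cdf(v0, a, b) + rng.normal(0, s, 3_000_000)
        vhat = stats.beta.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b)
        se = vhat.std() / np.sqrt(vhat.size)
        m_printed, var_printed = encode_moments(v0, s, (a, b))
        m_half, _ = encode_moments(v0, s, (a, b), delta_half=True)
        assert m_half == pytest.approx(vhat.mean(), abs=3 * se)
        assert abs(m_printed - vhat.mean()) > 3 * se
        # the variance expression holds for both variants
        assert var_printed == pytest.approx(vhat.var(), rel=0.05)

    def test_support_edge_rejected(self):
        with pytest.raises(ValueError):
            encode_moments(0.0, 0.05, (2.0, 3.0))


class TestRatingLikelihood:
    def test_change_of_variables_integrates_to_one(self):
        em = EncodingModel((2.0, 3.0), 0.03, 0.05)
        prior = stats.beta.pdf(0.4, 2.0, 3.0)
        val, _ = quad(lambda r: rating_likelihood(r, 0.4, em) / prior,
                      0, 1, limit=300)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_comparison_noise_flattens_density(self):
        lo = EncodingModel((2.0, 3.0), 0.03, 0.01)
        hi = EncodingModel((2.0, 3.0), 0.03, 0.2)
        peak = lo.g_map.g(encode_moments(0.4, 0.03, (2.0, 3.0))[0])
        assert rating_likelihood(peak, 0.4, lo) > rating_likelihood(peak, 0.4,
                                                                    hi)

    def test_kernel_mode_at_mapped_mean(self):
        em = EncodingModel((2.0, 3.0), 0.05, 0.02)
        mean, var = encode_moments(0.45, 0.05, (2.0, 3.0))
        r = np.linspace(0.05, 0.95, 901)
        # remove prior and Jacobian: the normal kernel should peak at g(mean)
        kern = (rating_likelihood(r, 0.45, em)
                / em.g_map.g_inv_prime(r))
        assert r[np.argmax(kern)] == pytest.approx(em.g_map.g(mean), abs=0.01)

    def test_edge_ratings_clipped_not_fatal(self):
        em = EncodingModel((2.0, 3.0), 0.03, 0.05)
        assert np.isfinite(rating_likelihood(0.0, 0.4, em, log=True))
        assert np.isfinite(rating_likelihood(1.0, 0.4, em, log=True))


class TestECChoiceProb:
    def test_full_symmetry(self):
        em = EncodingModel((1.2, 1.2), 0.05, 0.03)
        assert ec_choice_prob(0.5, 0.5, 0.5, 0.7, em) == pytest.approx(0.5)

    def test_full_effort_reduces_to_attention_free_form(self, rng):
        em = EncodingModel((1.5, 1.5), 0.05, 0.03)
        v1, v2, a = rng.random(40) * 0.8 + 0.1, rng.random(40) * 0.8 + 0.1, \
            rng.random(40)
        e1, var1 = encode_moments(v1, 0.05, (1.5, 1.5))
        e2, var2 = encode_moments(v2, 0.05, (1.5, 1.5))
        ref = stats.norm.cdf((e1 - e2) / np.sqrt(var1 + var2 + 0.03 ** 2))
        np.testing.assert_allclose(ec_choice_prob(v1, v2, a, 1.0, em), ref,
                                   atol=1e-12)

    def test_probabilities_sum_to_one_under_swap(self, rng):
        em = EncodingModel((1.2, 1.2), 0.05, 0.03)
        v1, v2, a = (rng.random(30) * 0.9 + 0.05 for _ in range(3))
        total = (ec_choice_prob(v1, v2, a, 0.6, em)
                 + ec_choice_prob(v2, v1, 1 - a, 0.6, em))
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_flat_prior_no_encoding_noise_is_attentional_probit(self, rng):
        # sigma_enc -> 0 under a flat prior: decoded means are the values
        # and the denominator is sigma_comp, i.e. the attentional RUM with
        # sigma = sigma_comp / sqrt(2)
        sc = 0.12
        em = EncodingModel((1.0, 1.0), 1e-9, sc)
        v1, v2, a = (rng.random(30) * 0.9 + 0.05 for _ in range(3))
        ref = attentional_rum_choice_prob(v1, v2, a, 0.6, sc / np.sqrt(2))
        np.testing.assert_allclose(ec_choice_prob(v1, v2, a, 0.6, em), ref,
                                   atol=1e-9)

    def test_sharper_discrimination_with_less_comparison_noise(self):
        lo = EncodingModel((1.2, 1.2), 0.02, 0.02)
        hi = EncodingModel((1.2, 1.2), 0.02, 0.3)
        assert ec_choice_prob(0.7, 0.5, 0.5, 1.0, lo) > \
            ec_choice_prob(0.7, 0.5, 0.5, 1.0, hi)


class TestRatingModel:
    def _ratings(self, rng, sigma_enc, sigma_comp, n_items=64):
        gm = GMap()
        vals = np.clip(stats.beta.rvs(2, 3, size=n_items,
                                      random_state=rng.integers(2 ** 31)),
                       0.02, 0.98)
        out = {}
        for i, v in enumerate(vals):
            mean, var = encode_moments(v, sigma_enc, (2.0, 3.0))
            x = rng.normal(mean, np.sqrt(var + sigma_comp ** 2), 2)
            out[f"i{i:02d}"] = gm.g(x)
        return vals, out

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError, match="rating variability"):
            RatingModel({f"i{j}": [0.5] for j in range(10)})

    def test_zero_encoding_noise_recovered_near_zero(self, rng):
        _, ratings = self._ratings(rng, 0.0, 0.05)
        res = RatingModel(ratings).fit(MCMCConfig(n_warmup=800, n_keep=400,
                                                  seed=0))
        assert np.median(res.draws["sigma_enc"]) < 0.03

    def test_values_rank_recovered(self, rng):
        vals, ratings = self._ratings(rng, 0.03, 0.05)
        res = RatingModel(ratings).fit(MCMCConfig(n_warmup=800, n_keep=400,
                                                  seed=1))
        rho = stats.spearmanr(vals, res.model.values).statistic
        assert rho > 0.95


class TestECChoiceModelPriors:
    def test_draws_respect_prior_bounds(self, rng):
        S, N = 4, 60
        cols = {k: [] for k in ("s", "vi", "vj", "a", "y", "c")}
        for s in range(S):
            vi, vj = rng.random(N), rng.random(N)
            a, c = rng.random(N), rng.random(N)
            y = rng.random(N) < 0.5
            cols["s"] += [s] * N
            cols["vi"] += list(np.clip(vi, 0.05, 0.95))
            cols["vj"] += list(np.clip(vj, 0.05, 0.95))
            cols["a"] += list(a)
            cols["y"] += list(y)
            cols["c"] += list(c)
        m = ECChoiceModel(cols["s"], cols["vi"], cols["vj"], cols["a"],
                          cols["y"], cols["c"], omega=(1.2, 1.2))
        res = m.fit(MCMCConfig(n_warmup=300, n_keep=200, seed=0))
        tb = res.draws["theta_base"]
        assert np.all((tb > -0.5) & (tb < 1.5))
        be = res.draws["beta_sigma_enc"]
        assert np.all((be > -0.2) & (be < 0.5))
        for name in ("sigma_enc_base", "sigma_comp_base"):
            assert np.all(res.draws[name] > 0)
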