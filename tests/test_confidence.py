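import numpy as np
import pytest
from scipy import stats

from valconf.confidence import (NormativePredictor, build_context_table,
                                expected_heuristic_confidence,
                                heuristic_confidence, normative_confidence)
from valconf.glam import drift_terms


def _contexts(rng, n=60):
    tv = rng.uniform(0.6, 1.4, n)
    vd = rng.choice([0.05, 0.1, 0.15, 0.2], n)
    hi, lo = (tv + vd) / 2, (tv - vd) / 2
    up_hi = rng.random(n) < 0.5
    return np.column_stack([np.where(up_hi, hi, lo),
                            np.where(up_hi, lo, hi),
                            rng.beta(1.3, 1.3, n)])


class TestHeuristic:
    @pytest.mark.parametrize("loser,expected", [
        (0.0, 1.0), (0.9, pytest.approx(0.1)), (-0.5, 1.5)])
    def test_balance_of_evidence(self, loser, expected):
        assert heuristic_confidence(loser, B=1.0) == expected

    def test_loser_at_bound_rejected(self):
        with pytest.raises(ValueError):
            heuristic_confidence(1.0, B=1.0)

    def test_expected_decreases_with_rt(self, base_params):
        rt = np.linspace(0.2, 3.5, 25)
        conf = expected_heuristic_confidence(rt, 0.4, base_params)
        assert np.all(np.diff(conf) < 0)

    def test_truncated_variant_matches_monte_carlo(self, base_params, rng):
        # mean of B - e with e ~ N((kR)t, sigma^2 t) conditioned below B
        t, R = 0.9, 0.45
        m = base_params.k * R * t
        s = base_params.sigma * np.sqrt(t)
        draws = m + s * rng.standard_normal(1_000_000)
        kept = draws[draws < base_params.B]
        mc = (base_params.B - kept).mean()
        se = kept.std() / np.sqrt(kept.size)
        out = expected_heuristic_confidence(t, R, base_params,
                                            loser_mean_variant="truncated")
        assert out == pytest.approx(mc, abs=3 * se)

    def test_as_printed_flips_the_mills_term(self, base_params):
        # the printed formula subtracts the Mills-ratio term that the
        # truncated-normal mean adds; the two variants straddle B - (kR)t
        t, R = 0.9, 0.45
        mid = base_params.B - base_params.k * R * t
        lo = expected_heuristic_confidence(t, R, base_params,
                                           loser_mean_variant="as_printed")
        hi = expected_heuristic_confidence(t, R, base_params,
                                           loser_mean_variant="truncated")
        assert lo < mid < hi
        assert hi - mid == pytest.approx(mid - lo, rel=1e-9)

    def test_noiseless_limit(self):
        from valconf.glam import GLAMParams
        p = GLAMParams(k=1.0, sigma=1e-9, tau=8.0, theta=0.6)
        out = expected_heuristic_confidence(0.5, 0.6, p,
                                            loser_mean_variant="truncated")
        assert out == pytest.approx(1.0 - 0.3, abs=1e-6)

    def test_mills_underflow_regime_finite(self, base_params):
        # beta very negative: Phi underflows; log-space path must survive
        out = expected_heuristic_confidence(50.0, 0.99, base_params)
        assert np.isfinite(out)


class TestContextTable:
    def test_determinism(self, base_params, rng):
        ctx = _contexts(rng)
        a = build_context_table(ctx, base_params, n_sim=4000, seed=5, dt=0.004)
        b = build_context_table(ctx, base_params, n_sim=4000, seed=5, dt=0.004)
        np.testing.assert_array_equal(a.table, b.table)

    def test_probabilities_and_conservation(self, base_params, rng):
        ctx = _contexts(rng)
        tab = build_context_table(ctx, base_params, n_sim=30_000, seed=2,
                                  dt=0.002)
        assert np.all((tab.table >= 0) & (tab.table <= 1))
        # count-weighted average of cells equals overall simulated accuracy
        w = tab.counts / tab.counts.sum()
        raw = (tab.table * (tab.counts + 1) - tab.marginal_accuracy)
        avg = (raw / np.maximum(tab.counts, 1) * w)[tab.counts > 0].sum()
        assert avg == pytest.approx(tab.marginal_accuracy, abs=1e-3)

    def test_full_effort_large_vd_near_certain(self, base_params):
        ctx = np.array([[0.9, 0.2, 0.5]])
        p = base_params.replace(theta=1.0)
        tab = build_context_table(ctx, p, n_sim=20_000, seed=0, dt=0.002)
        occupied = tab.counts > 20
        assert tab.table[occupied].min() > 0.9


class TestNormative:
    def test_output_in_unit_interval(self, base_params, rng):
        ctx = _contexts(rng)
        tab = build_context_table(ctx, base_params, n_sim=20_000, seed=1,
                                  dt=0.002)
        rt = rng.uniform(0.2, 2.0, 40)
        pc = normative_confidence(np.repeat("correct", 40), rt,
                                  ctx[:40, 0], ctx[:40, 1], ctx[:40, 2], tab)
        assert np.all((pc >= 0) & (pc <= 1))

    def test_decreases_with_rt(self, base_params, rng):
        ctx = _contexts(rng)
        tab = build_context_table(ctx, base_params, n_sim=40_000, seed=3,
                                  dt=0.002)
        rt = np.linspace(0.3, 2.5, 12)
        pc = normative_confidence(np.repeat("correct", 12), rt,
                                  np.full(12, 0.7), np.full(12, 0.55),
                                  np.full(12, 0.5), tab)
        assert pc[-1] < pc[0]
        assert np.mean(np.diff(pc) < 0) > 0.7   # monotone trend, binned noise

    def test_single_context_low_noise_approaches_one(self):
        from valconf.glam import GLAMParams
        p = GLAMParams(k=1.5, sigma=0.05, tau=8.0, theta=1.0)
        ctx = np.array([[0.8, 0.4, 0.5]])
        tab = build_context_table(ctx, p, n_sim=5000, seed=0, dt=0.002)
        rt_typ = np.quantile(tab.rt_edges, 0.5)
        pc = normative_confidence("correct", rt_typ, 0.8, 0.4, 0.5, tab)
        assert pc > 0.95

    def test_increases_with_theta_on_fixed_grid(self, base_params, rng):
        # the central qualitative property of the probability-correct readout
        ctx = _contexts(rng, n=100)
        means = []
        for theta in (0.2, 0.6, 1.0):
            p = base_params.replace(theta=theta)
            tab = build_context_table(ctx, p, n_sim=25_000, seed=7, dt=0.002)
            rt = np.full(50, 0.8)
            pc = normative_confidence(np.repeat("correct", 50), rt,
                                      ctx[:50, 0], ctx[:50, 1], ctx[:50, 2],
                                      tab, theta=theta)
            means.append(pc.mean())
        assert means[0] < means[1] < means[2]


class TestNormativePredictor:
    def test_trialwise_latents_shape_and_range(self, base_params, rng):
        ctx = _contexts(rng, n=50)
        pred = NormativePredictor(ctx, base_params, n_sim=6000, seed=0,
                                  dt=0.004)
        n = 30
        theta = rng.uniform(0.3, 0.9, n)
        k = rng.uniform(1.0, 2.0, n)
        out = pred.predict(np.repeat("correct", n), rng.uniform(0.3, 1.5, n),
                           ctx[:n, 0], ctx[:n, 1], ctx[:n, 2], theta=theta,
                           k=k)
        assert out.shape == (n,)
        assert np.all((out >= 0) & (out <= 1))
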