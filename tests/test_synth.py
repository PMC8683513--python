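import numpy as np
import pytest
from scipy import stats

from valconf.data import apply_exclusion
from valconf.glam import GLAMParams, simulate_trials
from valconf.joint import JointHyper
from valconf.synth import (GeneratorConfig, build_trial_set, generate_dataset,
                           sample_true_values, simulate_ratings,
                           simulate_session)


class TestTrueValues:
    def test_uniform_prior_mean(self):
        v = sample_true_values(100_000, (1.0, 1.0), seed=1)
        assert v.mean() == pytest.approx(0.5, abs=3 * 0.2887 / np.sqrt(1e5))

    def test_beta_mean_closed_form(self):
        v = sample_true_values(100_000, (2.0, 5.0), seed=2)
        se = v.std() / np.sqrt(v.size)
        assert v.mean() == pytest.approx(2 / 7, abs=3 * se)

    def test_seed_determinism(self):
        a = sample_true_values(50, (1.2, 1.2), seed=7)
        b = sample_true_values(50, (1.2, 1.2), seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            sample_true_values(10, (0.0, 1.0), seed=0)


class TestRatings:
    def test_zero_noise_phases_identical(self):
        v = np.linspace(0.1, 0.9, 9)
        recs = simulate_ratings(v, 0.0, 0.0, (1.2, 1.2), seed=0)
        by_item = {}
        for r in recs:
            by_item.setdefault(r.item_id, []).append(r.rating)
        for rs in by_item.values():
            assert rs[0] == pytest.approx(rs[1], abs=1e-12)

    def test_uniform_prior_rating_sd_tracks_encoding_noise(self, rng):
        # flat prior: phi' = 1, internal sd = sigma_enc; on the rating scale
        # this is scaled by the slope of the logistic map at each value
        from valconf.efficient_coding import GMap
        sigma_enc = 0.04
        v = np.full(4000, 0.5)
        recs = simulate_ratings(v, sigma_enc, 0.0, (1.0, 1.0), phases=2,
                                seed=3)
        r = np.array([rec.rating for rec in recs])
        gm = GMap()
        jac = gm.slope * 0.25    # derivative of the map at midscale
        assert r.std() == pytest.approx(sigma_enc * jac, rel=0.05)

    def test_variance_monotone_in_encoding_noise(self):
        v = np.linspace(0.15, 0.85, 40)
        out = []
        for s in (0.02, 0.05, 0.1):
            recs = simulate_ratings(np.tile(v, 40), s, 0.0, (1.2, 1.2),
                                    seed=4)
            by_item = {}
            for r in recs:
                by_item.setdefault(r.item_id, []).append(r.rating)
            out.append(np.mean([np.var(x, ddof=1)
                                for x in by_item.values()]))
        assert out[0] < out[1] < out[2]


class TestTrialSet:
    def test_balance_across_levels_and_location(self, rng):
        ratings = {f"i{j:03d}": float(x)
                   for j, x in enumerate(rng.uniform(0.02, 0.98, 64))}
        trials = build_trial_set(ratings, (0.05, 0.10, 0.15, 0.20), 240,
                                 seed=0)
        assert len(trials) <= 240
        levels = {}
        up_count = 0
        for t in trials:
            d = abs(t["v_upper"] - t["v_lower"])
            lv = min((0.05, 0.10, 0.15, 0.20), key=lambda x: abs(x - d))
            assert abs(d - lv) <= 0.0125 + 1e-12
            levels[lv] = levels.get(lv, 0) + 1
            up_count += t["v_upper"] > t["v_lower"]
        if len(levels) == 4:
            assert max(levels.values()) - min(levels.values()) <= 1
        # higher-rated item on top about half the time
        p = stats.binomtest(up_count, len(trials), 0.5).pvalue
        assert p > 1e-4

    def test_two_items_single_pair(self):
        trials = build_trial_set({"a": 0.6, "b": 0.55}, (0.05,), 240, seed=0)
        assert len(trials) == 1

    def test_infeasible_level_warns_and_underfills(self):
        ratings = {"a": 0.2, "b": 0.25}
        with pytest.warns(UserWarning, match="no feasible pairs"):
            trials = build_trial_set(ratings, (0.05, 0.5), 10, seed=0)
        assert all(abs(abs(t["v_upper"] - t["v_lower"]) - 0.05) <= 0.0125
                   for t in trials)


class TestSession:
    def test_symmetric_values_yield_even_choices(self):
        glam = GLAMParams(k=1.5, sigma=0.4, tau=12.0, theta=1.0)
        linking = JointHyper(mu=(0.0, 1.0, 1.5), sigma=(1.0, 1e-4, 1e-4),
                            rho=(0.0, 0.0, 0.0))
        stubs = [{"item_upper": "a", "item_lower": "b", "v_upper": 0.5,
                  "v_lower": 0.5}] * 2000
        ds, truth = simulate_session(stubs, glam, linking, seed=5,
                                     gaze_beta=(50.0, 50.0))
        p = truth.choice_upper.mean()
        assert p == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2000))

    def test_larger_vd_more_consistent_and_faster(self, small_session):
        ds, _ = small_session
        df = ds.to_frame()
        lo = df[df.VD < df.VD.median()]
        hi = df[df.VD >= df.VD.median()]
        assert (hi.consistency == "consistent").mean() > \
            (lo.consistency == "consistent").mean()
        assert hi.rt_s.mean() < lo.rt_s.mean()

    def test_injected_correlation_reaches_reports(self):
        cfg = GeneratorConfig(seed=9, max_trials=240,
                              linking=JointHyper(mu=(0, 0.6, 1.5),
                                                 sigma=(1.0, 0.25, 0.25),
                                                 rho=(0.9, 0.3, 0.3)))
        ds, truth = generate_dataset(cfg)
        r = np.corrcoef(truth.confidence, truth.theta_n)[0, 1]
        assert r == pytest.approx(0.9, abs=0.06)

    def test_zero_spread_linking_reduces_to_fixed_simulator(self):
        # degenerate linking = fixed-parameter race: same RT distribution
        glam = GLAMParams(k=1.5, sigma=0.4, tau=12.0, theta=0.6)
        linking = JointHyper(mu=(0.0, glam.theta, glam.k),
                             sigma=(1.0, 1e-6, 1e-6), rho=(0.0, 0.0, 0.0))
        stubs = [{"item_upper": "a", "item_lower": "b", "v_upper": 0.7,
                  "v_lower": 0.55}] * 4000
        ds, truth = simulate_session(stubs, glam, linking, seed=3,
                                     gaze_beta=(1e6, 1e6))
        fixed = simulate_trials(np.full(4000, 0.7), np.full(4000, 0.55),
                                np.full(4000, 0.5), glam, dt=0.002, rng=4)
        ks = stats.ks_2samp(truth.rt_s, fixed["rt_s"])
        assert ks.pvalue > 0.01
        assert abs(truth.choice_upper.mean()
                   - fixed["choice_upper"].mean()) < 0.03

    def test_generated_sessions_survive_validators_and_exclusion(
            self, small_session):
        ds, _ = small_session
        out = apply_exclusion(ds)
        assert len(out.trials) == len(ds.valid_trials())

    def test_generator_determinism(self):
        cfg = GeneratorConfig(seed=123, max_trials=60)
        a, ta = generate_dataset(cfg)
        b, tb = generate_dataset(cfg)
        assert [t.rt_s for t in a.trials] == [t.rt_s for t in b.trials]
        assert ta.equals(tb)
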