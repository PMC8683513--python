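"""Synthetic sessions with the statistical structure the analyses assume.

A generated session emulates the behavioral study design: latent item
values drawn from a Beta prior, two noisy rating phases produced by the
efficient-coding generative process, a balanced trial set at four
value-difference levels (5/10/15/20% of the rating scale, at most 240
trials balanced over the location of the higher-rated item), dwell shares
from a Beta distribution, choices and reaction times from the
gaze-weighted race, and confidence reports tied to trial-varying
(theta_n, k_n) latents through the multivariate-normal linking
distribution.

The default generator settings are the study conditions: 64 items, four
VD levels, <= 240 trials, a 4-second response deadline, race parameters
that put reaction times in the sub-second range typical of food-choice
experiments, and mild gaze dispersion (Beta(3, 3) dwell shares).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import FixationRecord, RatingRecord, SubjectDataset, Trial
from .efficient_coding import GMap, encode_moments
from .glam import GLAMParams, simulate_trials
from .joint import JointHyper

__all__ = ["GeneratorConfig", "recovery_config", "sample_true_values",
           "simulate_ratings", "build_trial_set", "simulate_session",
           "generate_dataset", "generate_population", "DEFAULT_GLAM",
           "DEFAULT_LINKING"]

# Race parameters put simulated sessions in the human range for two-item
# food choice: mean RT ~0.9 s, RT coefficient of variation ~0.4, choice
# consistency ~0.8 at the 5-20% rating-difference levels.
DEFAULT_GLAM = GLAMParams(k=1.5, sigma=0.4, tau=12.0, theta=0.6)
DEFAULT_LINKING = JointHyper(mu=(0.0, 0.6, 1.5), sigma=(1.0, 0.25, 0.25),
                             rho=(0.5, 0.7, 0.4))


@dataclass(frozen=True)
class GeneratorConfig:
    n_items: int = 64
    # Symmetric broad value prior: the item set spans the whole scale, with
    # low prior density (hence high encoding noise) at both extremes.
    omega: tuple = (1.2, 1.2)
    sigma_enc: float = 0.05
    sigma_comp: float = 0.03
    glam: GLAMParams = DEFAULT_GLAM
    linking: JointHyper = DEFAULT_LINKING
    vd_levels: tuple = (0.05, 0.10, 0.15, 0.20)
    vd_tolerance: float = 0.0125       # half the inter-level spacing
    max_trials: int = 240
    gaze_beta: tuple = (2.0, 2.0)
    # preferential looking: mean dwell share shifts toward the currently
    # higher-valued item by gaze_value_coupling * (value difference)
    gaze_value_coupling: float = 1.2
    confidence_source: str = "linking"   # linking | heuristic | normative
    confidence_noise: float = 0.25       # reporting noise, fraction of sd
    encoding_noise_in_choice: bool = False
    deadline_s: float = 4.0
    dt: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.sigma_enc < 0 or self.sigma_comp < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not all(0 < v < 1 for v in self.vd_levels):
            raise ValueError("vd_levels must be scale fractions in (0, 1)")
        if self.max_trials > 240:
            raise ValueError("sessions cap at 240 trials")


def recovery_config(**kw) -> GeneratorConfig:
    """Generator preset for parameter/model-recovery studies.

    Dwell shares are drawn independently of the values (exogenous gaze,
    Beta(1.3, 1.3)) and choices run on the rating means, so the race model
    being fitted is exactly the data-generating process; the behavioral-
    emulation defaults (preferential looking, encoding noise at choice)
    deliberately violate it.  The race uses a slightly shallower evidence
    transform (tau = 8) so that drift rates stay off the logistic
    saturation range across the four VD levels.
    """
    base = dict(glam=GLAMParams(k=1.5, sigma=0.4, tau=8.0, theta=0.6),
                gaze_beta=(1.3, 1.3), gaze_value_coupling=0.0,
                encoding_noise_in_choice=False)
    base.update(kw)
    return GeneratorConfig(**base)


def sample_true_values(n_items, omega, seed=None) -> np.ndarray:
    """i.i.d. subjective values from the Beta(omega) prior on [0, 1]."""
    if n_items < 2:
        raise ValueError("need at least two items")
    a, b = omega
    if a <= 0 or b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    return rng.beta(a, b, size=n_items)


def simulate_ratings(values, sigma_enc, sigma_comp, omega, phases=2,
                     seed=None, g_map: GMap | None = None,
                     delta_half=False) -> list[RatingRecord]:
    """Noisy rating phases from the efficient-coding generative process.

    Each rating is a draw with mean E[vhat | v0] and variance
    Var[vhat | v0] + sigma_comp^2 (moments from the encoding model),
    mapped to the physical scale through g and clipped inside (0, 1).
    With both noise terms at zero the ratings equal the transformed values
    exactly.
    """
    g_map = g_map or GMap()
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if np.any((values <= 0) | (values >= 1)):
        raise ValueError("values must lie strictly inside (0, 1)")
    mean, var = encode_moments(values, sigma_enc, omega,
                               delta_half=delta_half)
    sd = np.sqrt(var + sigma_comp ** 2)
    out = []
    for phase in range(1, phases + 1):
        x = mean + sd * rng.standard_normal(values.size)
        r = np.clip(g_map.g(x), 1e-4, 1 - 1e-4)
        out.extend(RatingRecord(item_id=f"item{i:03d}", phase=phase,
                                rating=float(r[i]))
                   for i in range(values.size))
    return out


def build_trial_set(mean_ratings: dict, vd_levels=(0.05, 0.10, 0.15, 0.20),
                    max_trials=240, seed=None, tolerance=0.0125):
    """Balanced pairs of items across VD levels and screen location.

    mean_ratings : item_id -> mean rating across phases.
    Pairs whose mean-rating difference falls within ``tolerance`` of a
    level are candidates for it; each level receives an equal quota (the
    remainder spread over the first levels) and the higher-rated item is
    placed in the upper position on alternating trials.  Infeasible levels
    are under-filled with a warning.

    Returns a list of dicts with keys item_upper/item_lower/v_upper/v_lower.
    """
    rng = np.random.default_rng(seed)
    items = sorted(mean_ratings)
    vals = np.array([mean_ratings[i] for i in items])
    n_lv = len(vd_levels)
    quota = [max_trials // n_lv + (1 if i < max_trials % n_lv else 0)
             for i in range(n_lv)]
    trials = []
    for lv, q in zip(vd_levels, quota):
        cand = []
        for i in range(len(items)):
            for j in range(len(items)):
                if i == j:
                    continue
                d = vals[i] - vals[j]
                if abs(d - lv) <= tolerance:
                    cand.append((i, j))   # i is the higher-rated item
        if not cand:
            warnings.warn(f"VD level {lv}: no feasible pairs; level unfilled")
            continue
        if len(cand) < q:
            warnings.warn(f"VD level {lv}: only {len(cand)} of {q} pairs")
        order = rng.permutation(len(cand))[:q]
        for t, idx in enumerate(order):
            hi, lo = cand[idx]
            up_hi = t % 2 == 0
            iu, il = (hi, lo) if up_hi else (lo, hi)
            trials.append({"item_upper": items[iu], "item_lower": items[il],
                           "v_upper": float(vals[iu]),
                           "v_lower": float(vals[il])})
    rng.shuffle(trials)
    return trials


def _make_fixations(trial_id, g_upper, rt_s, rng):
    """Bookkeeping fixation records whose dwell shares re-aggregate to g.

    Four alternating option fixations (two per option) spanning the RT;
    not a model of saccade dynamics.
    """
    total = max(rt_s * 1000.0, 40.0)
    up = g_upper * total
    low = total - up
    durs = [up * 0.5, low * 0.5, up * 0.5, low * 0.5]
    targets = ["upper", "lower", "upper", "lower"]
    if rng.random() < 0.5:
        durs = durs[1:] + durs[:1]
        targets = targets[1:] + targets[:1]
    t = 0.0
    out = []
    for d, tg in zip(durs, targets):
        if d <= 1e-3:   # sub-microsecond dwell: drop, keeps offsets > onsets
            continue
        out.append(FixationRecord(trial_id=trial_id, target=tg,
                                  onset_ms=t, offset_ms=t + d))
        t += d
    return out


def simulate_session(trial_stubs, glam: GLAMParams, linking: JointHyper,
                     confidence_source="linking", seed=None,
                     gaze_beta=(1.3, 1.3), gaze_value_coupling=0.0,
                     deadline_s=4.0, dt=0.002,
                     retry_cap=10, confidence_noise=0.25, subject_id="sim00",
                     ratings=None, item_vars=None, choice_values=None,
                     normative_predictor_kw=None):
    """Run the race across a trial set and emit a full SubjectDataset.

    Per trial, (c, theta_n, k_n) is drawn from the linking distribution,
    the dwell share from Beta(gaze_beta), and the race from the
    discrete-time simulator.  Races exceeding the deadline are resampled
    up to ``retry_cap`` times, then flagged as timeouts (invalid).

    confidence_source selects the reported confidence: "linking" uses the
    multivariate-normal confidence propensity directly (so the injected
    correlations with theta_n, k_n hold for the reports); "heuristic" and
    "normative" report the corresponding generative-model readout at the
    trial latents plus reporting noise.  All variants are min-max rescaled
    to [0, 1] within the session.

    choice_values : optional (n, 2) array of value signals actually fed to
    the race (e.g. fresh noisy estimates when emulating encoding
    variability); the recorded trial values stay at the rating means.

    Returns (SubjectDataset, truth DataFrame with the per-trial latents).
    """
    rng = np.random.default_rng(seed)
    n = len(trial_stubs)
    lat = rng.multivariate_normal(np.asarray(linking.mu), linking.cov(),
                                  size=n, method="cholesky")
    c_prop, theta_n, k_n = lat[:, 0], lat[:, 1], np.maximum(lat[:, 2], 1e-2)
    v_up = np.array([t["v_upper"] for t in trial_stubs])
    v_low = np.array([t["v_lower"] for t in trial_stubs])
    if choice_values is not None:
        cv = np.asarray(choice_values, dtype=float)
        sim_v_up, sim_v_low = cv[:, 0], cv[:, 1]
    else:
        sim_v_up, sim_v_low = v_up, v_low
    if gaze_value_coupling:
        # preferential looking tracks the decision-time value signals
        kappa = float(sum(gaze_beta))
        m = np.clip(0.5 + gaze_value_coupling * (sim_v_up - sim_v_low),
                    0.05, 0.95)
        g_up = rng.beta(m * kappa, (1.0 - m) * kappa)
    else:
        g_up = rng.beta(*gaze_beta, size=n)

    out = simulate_trials(sim_v_up, sim_v_low, g_up, glam, dt=dt,
                          deadline=deadline_s, rng=rng,
                          theta=theta_n, k=k_n)
    for _ in range(retry_cap):
        to = out["timeout"]
        if not to.any():
            break
        redo = simulate_trials(sim_v_up[to], sim_v_low[to], g_up[to], glam,
                               dt=dt, deadline=deadline_s, rng=rng,
                               theta=theta_n[to], k=k_n[to])
        for key in out:
            out[key][to] = redo[key]
    timeout = out["timeout"]
    rt = np.minimum(out["rt_s"], deadline_s)
    chose_up = out["choice_upper"]
    loser_e = out["loser_evidence"]

    if confidence_source == "linking":
        z = c_prop
    elif confidence_source == "heuristic":
        z = glam.B - loser_e
        z = z + confidence_noise * np.std(z) * rng.standard_normal(n)
    elif confidence_source == "normative":
        from .confidence import NormativePredictor
        kw = dict(n_sim=15_000, seed=int(rng.integers(2 ** 20)))
        kw.update(normative_predictor_kw or {})
        pred = NormativePredictor(np.column_stack([v_up, v_low, g_up]),
                                  glam, **kw)
        cls = np.where(chose_up, sim_v_up >= sim_v_low, sim_v_low >= sim_v_up)
        z = pred.predict(cls, rt, v_up, v_low, g_up, theta=theta_n, k=k_n)
        z = z + confidence_noise * np.std(z) * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown confidence_source {confidence_source!r}")
    lo, hi = z.min(), z.max()
    conf = (z - lo) / (hi - lo) if hi > lo else np.full(n, 0.5)

    trials, fixations = [], {}
    for i, stub in enumerate(trial_stubs):
        tid = i + 1
        var_up = var_low = None
        if item_vars is not None:
            var_up = float(item_vars.get(stub["item_upper"], 0.0))
            var_low = float(item_vars.get(stub["item_lower"], 0.0))
        tr = Trial(trial_id=tid, item_upper=stub["item_upper"],
                   item_lower=stub["item_lower"], v_upper=stub["v_upper"],
                   v_lower=stub["v_lower"], var_upper=var_up,
                   var_lower=var_low, choice="upper" if chose_up[i] else "lower",
                   rt_s=float(rt[i]), confidence=float(conf[i]),
                   g_upper=float(g_up[i]), valid=not bool(timeout[i]))
        trials.append(tr)
        fixations[tid] = _make_fixations(tid, g_up[i], rt[i], rng)

    ds = SubjectDataset(subject_id=subject_id, ratings=list(ratings or []),
                        trials=trials, fixations=fixations)
    truth = pd.DataFrame({
        "trial": np.arange(1, n + 1), "c_propensity": c_prop,
        "theta_n": theta_n, "k_n": k_n, "g_upper": g_up,
        "loser_evidence": loser_e, "choice_upper": chose_up,
        "rt_s": rt, "confidence": conf, "timeout": timeout})
    return ds, truth


def generate_dataset(config: GeneratorConfig, subject_id="sim00"):
    """Full pipeline: values -> ratings -> trial set -> simulated session."""
    rng = np.random.default_rng(config.seed)
    values = np.clip(sample_true_values(config.n_items, config.omega,
                                        seed=rng.integers(2 ** 31)),
                     0.02, 0.98)
    recs = simulate_ratings(values, config.sigma_enc, config.sigma_comp,
                            config.omega, seed=rng.integers(2 ** 31))
    by_item: dict[str, list[float]] = {}
    for r in recs:
        by_item.setdefault(r.item_id, []).append(r.rating)
    means = {i: float(np.mean(v)) for i, v in by_item.items()}
    variances = {i: float(np.var(v, ddof=1)) for i, v in by_item.items()}
    stubs = build_trial_set(means, config.vd_levels, config.max_trials,
                            seed=rng.integers(2 ** 31),
                            tolerance=config.vd_tolerance)
    choice_values = None
    if config.encoding_noise_in_choice:
        # fresh noisy estimate of each displayed item at choice time
        idx = {f"item{i:03d}": i for i in range(config.n_items)}
        gm = GMap()
        mean, var = encode_moments(values, config.sigma_enc, config.omega)
        sd = np.sqrt(var + config.sigma_comp ** 2)
        cv = np.empty((len(stubs), 2))
        for t, st in enumerate(stubs):
            iu, il = idx[st["item_upper"]], idx[st["item_lower"]]
            cv[t, 0] = gm.g(mean[iu] + sd[iu] * rng.standard_normal())
            cv[t, 1] = gm.g(mean[il] + sd[il] * rng.standard_normal())
        choice_values = cv
    ds, truth = simulate_session(
        stubs, config.glam, config.linking,
        confidence_source=config.confidence_source,
        seed=rng.integers(2 ** 31), gaze_beta=config.gaze_beta,
        gaze_value_coupling=config.gaze_value_coupling,
        deadline_s=config.deadline_s, dt=config.dt,
        confidence_noise=config.confidence_noise, subject_id=subject_id,
        ratings=recs, item_vars=variances, choice_values=choice_values)
    return ds, truth


def generate_population(config: GeneratorConfig, n_subjects, seed=None):
    """Independent sessions for several subjects (seeds derived per subject)."""
    base = config.seed if seed is None else seed
    out = []
    for s in range(n_subjects):
        cfg = replace(config, seed=base + 101 * s + 1)
        out.append(generate_dataset(cfg, subject_id=f"sim{s:02d}"))
    return out
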