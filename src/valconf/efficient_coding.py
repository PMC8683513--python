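"""Efficient-coding model of subjective valuation.

An item's latent subjective value ``v0`` (on (0, 1)) is encoded by a
capacity-limited system whose resolution is allocated according to the
subject's value prior p(v; omega) (a Beta distribution here): encoding
happens on the uniformized scale u = F(v0) with constant noise sigma_enc,
and decoding applies the prior quantile function phi = F^{-1}.  Second-order
expansion gives the decoded estimate's moments

    E[vhat | v0]   ~ v0 + phi'' * sigma_enc^2
    Var[vhat | v0] ~ (phi')^2 * sigma_enc^2

with phi' = 1/p(v0) and phi'' = -p'(v0)/p(v0)^3 evaluated at F(v0).  The
``delta_half`` flag optionally inserts the conventional 1/2 factor in the
bias term (default off, matching the printed moment expressions; the test
suite's Monte-Carlo oracle documents that the 1/2 variant is the one that
matches the generative simulation).

Observed slider ratings live on the physical scale through a fixed
logistic map g; the rating likelihood adds value-unspecific comparison
noise sigma_comp after decoding:

    p(rating) = N(g^-1(rating); E[vhat|v0], Var[vhat|v0] + sigma_comp^2)
                * p(v0; omega) * (g^-1)'(rating)

Choice probabilities between two encoded items follow a probit rule on
the decoded means with the summed decoding variances plus comparison
noise in the denominator, optionally weighted by dwell shares A_i and the
attentional effort theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, log_ndtr, logit, ndtr

from .engine import MCMCConfig, diagnostics

__all__ = ["GMap", "EncodingModel", "encode_moments", "rating_likelihood",
           "RatingModel", "RatingModelResults", "ec_choice_prob",
           "ECChoiceModel", "ECChoiceResults"]

_EPS = 1e-4


@dataclass(frozen=True)
class GMap:
    """Logistic map from the subjective to the physical rating scale.

    g(x) = expit(slope * (x - mid)).  The midpoint sits at the center of
    the unit value range; the default slope spreads (0, 1) over ~90% of
    the physical scale.
    """

    slope: float = 6.0
    mid: float = 0.5

    def g(self, x):
        return expit(self.slope * (np.asarray(x, dtype=float) - self.mid))

    def g_inv(self, v):
        v = np.clip(np.asarray(v, dtype=float), _EPS, 1 - _EPS)
        return self.mid + logit(v) / self.slope

    def g_inv_prime(self, v):
        v = np.clip(np.asarray(v, dtype=float), _EPS, 1 - _EPS)
        return 1.0 / (self.slope * v * (1.0 - v))


@dataclass
class EncodingModel:
    """Prior, noise and mapping parameters of the valuation stage."""

    omega: tuple  # Beta(a, b) prior shape parameters
    sigma_enc: float
    sigma_comp: float
    values: np.ndarray | None = None       # latent item values v_1..M
    g_map: GMap = field(default_factory=GMap)
    delta_half: bool = False

    def __post_init__(self):
        a, b = self.omega
        if a <= 0 or b <= 0:
            raise ValueError("Beta prior shape parameters must be positive")
        if self.sigma_enc < 0 or self.sigma_comp < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _beta_pdf_and_dpdf(v0, a, b):
    v0 = np.asarray(v0, dtype=float)
    p = stats.beta.pdf(v0, a, b)
    dp = p * ((a - 1.0) / v0 - (b - 1.0) / (1.0 - v0))
    return p, dp


def encode_moments(v0, sigma_enc, omega, delta_half=False):
    """(mean, variance) of the decoded estimate vhat given true value v0.

    phi', phi'' are computed analytically from the Beta prior density
    (phi' = 1/p, phi'' = -p'/p^3); no numerical differentiation.
    """
    a, b = omega
    v0 = np.asarray(v0, dtype=float)
    if np.any((v0 <= 0) | (v0 >= 1)):
        raise ValueError("v0 must lie strictly inside (0, 1)")
    p, dp = _beta_pdf_and_dpdf(v0, a, b)
    if np.any(p <= 0) or not np.all(np.isfinite(dp)):
        raise ValueError("prior density degenerate at v0; shrink the support "
                         "or use milder prior shapes")
    phi1 = 1.0 / p
    phi2 = -dp / p ** 3
    bias = phi2 * sigma_enc ** 2
    if delta_half:
        bias = 0.5 * bias
    mean = v0 + bias
    var = phi1 ** 2 * sigma_enc ** 2
    return mean, var


def rating_likelihood(rating, v0, model: EncodingModel, log=False):
    """Joint density of (rating, v0) on the physical rating scale.

    Ratings at exactly 0 or 1 are clipped inward by 1e-4.
    """
    r = np.asarray(rating, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("ratings must lie in [0, 1]")
    r = np.clip(r, _EPS, 1 - _EPS)
    mean, var = encode_moments(v0, model.sigma_enc, model.omega,
                               delta_half=model.delta_half)
    tot = var + model.sigma_comp ** 2
    x = model.g_map.g_inv(r)
    ll = (-0.5 * (np.log(2 * np.pi * tot) + (x - mean) ** 2 / tot)
          + stats.beta.logpdf(v0, *model.omega)
          + np.log(model.g_map.g_inv_prime(r)))
    return ll if log else np.exp(ll)


def ec_choice_prob(v_i, v_j, A_i, theta, model: EncodingModel, log=False):
    """Probit choice probability between two encoded items.

    Numerator: A_i E_i - A_j E_j + theta (A_j E_i - A_i E_j) with
    A_j = 1 - A_i; denominator: sqrt(Var_i + Var_j + sigma_comp^2).
    theta = 1 recovers the attention-free probit on the decoded means.
    """
    A_i = np.asarray(A_i, dtype=float)
    A_j = 1.0 - A_i
    e_i, var_i = encode_moments(v_i, model.sigma_enc, model.omega,
                                delta_half=model.delta_half)
    e_j, var_j = encode_moments(v_j, model.sigma_enc, model.omega,
                                delta_half=model.delta_half)
    num = A_i * e_i - A_j * e_j + theta * (A_j * e_i - A_i * e_j)
    den = np.sqrt(var_i + var_j + model.sigma_comp ** 2)
    z = num / den
    return log_ndtr(z) if log else ndtr(z)


# ---------------------------------------------------------------------------
# Rating-model fitting (Gibbs/Metropolis over values, prior and noises)


@dataclass
class RatingModelResults:
    model: EncodingModel          # posterior-median plug-in
    draws: dict                   # posterior draws of omega, sigmas
    value_draws: np.ndarray       # (n_draws, M)
    item_ids: list
    diagnostics: object
    n_items: int

    def summary(self) -> str:
        lines = ["Efficient-coding rating model",
                 "items = %d" % self.n_items,
                 "%-12s %10s %18s" % ("param", "median", "94% interval")]
        for name in ("omega_a", "omega_b", "sigma_enc", "sigma_comp"):
            d = self.draws[name]
            lo, hi = np.percentile(d, [3, 97])
            lines.append("%-12s %10.4f    [%8.4f, %8.4f]"
                         % (name, np.median(d), lo, hi))
        return "\n".join(lines)


class RatingModel:
    """Fit the efficient-coding rating likelihood to two-phase ratings.

    Parameters
    ----------
    ratings : mapping item_id -> sequence of ratings (one per phase).
        Two phases are required for most items: the model separates
        encoding noise from comparison noise through the value-dependence
        of the across-phase variance, which single-rating datasets cannot
        provide.
    """

    def __init__(self, ratings: dict, g_map: GMap | None = None,
                 delta_half: bool = False):
        self.item_ids = sorted(ratings)
        counts = [len(ratings[i]) for i in self.item_ids]
        if np.mean(np.asarray(counts) >= 2) < 0.5:
            raise ValueError(
                "encoding/comparison noise separation requires rating "
                "variability: supply >= 2 rating phases per item")
        self.ratings = [np.clip(np.asarray(ratings[i], float), _EPS, 1 - _EPS)
                        for i in self.item_ids]
        self.g_map = g_map or GMap()
        self.delta_half = delta_half
        self.M = len(self.item_ids)
        # flattened (item, rating) pairs for a fully vectorized likelihood
        self._item_of = np.concatenate(
            [np.full(len(r), m) for m, r in enumerate(self.ratings)])
        flat = np.concatenate(self.ratings)
        self._x = self.g_map.g_inv(flat)
        self._jac_sum = np.zeros(self.M)
        np.add.at(self._jac_sum, self._item_of,
                  np.log(self.g_map.g_inv_prime(flat)))
        self._n_per_item = np.bincount(self._item_of, minlength=self.M)

    def _loglik_items(self, values, a, b, s_enc, s_comp):
        mean, var = encode_moments(values, s_enc, (a, b),
                                   delta_half=self.delta_half)
        tot = var + s_comp ** 2
        prior = stats.beta.logpdf(values, a, b)
        resid2 = np.zeros(self.M)
        np.add.at(resid2, self._item_of,
                  (self._x - mean[self._item_of]) ** 2)
        out = (-0.5 * (self._n_per_item * np.log(2 * np.pi * tot)
                       + resid2 / tot) + self._jac_sum)
        return out + prior

    def fit(self, config: MCMCConfig | None = None) -> RatingModelResults:
        """Metropolis-within-Gibbs posterior sampling.

        Item values are updated jointly with independent per-item
        proposals (they are conditionally independent given the shared
        parameters); (omega, log sigma_enc, log sigma_comp) is an adaptive
        block.
        """
        config = config or MCMCConfig(n_warmup=600, n_keep=400)
        all_draws = {k: [] for k in ("omega_a", "omega_b", "sigma_enc",
                                     "sigma_comp")}
        value_draws = []
        chain_store = []
        for chain in range(config.n_chains):
            rng = np.random.default_rng(config.seed * 977 + chain)
            means = np.array([r.mean() for r in self.ratings])
            values = np.clip(self.g_map.g_inv(means), 0.02, 0.98)
            hyp = np.array([np.log(2.0), np.log(2.0), np.log(0.05),
                            np.log(0.05)])
            hyp += 0.05 * rng.standard_normal(4)
            step_v = 0.05
            step_h = np.array([0.15, 0.15, 0.3, 0.3])
            ll = self._loglik_items(values, *np.exp(hyp))
            keep = {k: [] for k in all_draws}
            vkeep = []
            total = config.n_warmup + config.n_keep * config.thinning
            for it in range(total):
                # item-value block: independent symmetric proposals
                prop = values + step_v * rng.standard_normal(self.M)
                inside = (prop > 1e-3) & (prop < 1 - 1e-3)
                prop = np.where(inside, prop, values)
                ll_prop = self._loglik_items(prop, *np.exp(hyp))
                acc = (np.log(rng.uniform(size=self.M)) < ll_prop - ll) & inside
                values = np.where(acc, prop, values)
                ll = np.where(acc, ll_prop, ll)
                # hyperparameter block
                hprop = hyp + step_h * rng.standard_normal(4)
                if np.all(np.abs(hprop) < 8):
                    a, b, se, sc = np.exp(hprop)
                    ll_h = self._loglik_items(values, a, b, se, sc)
                    if np.log(rng.uniform()) < ll_h.sum() - ll.sum():
                        hyp, ll = hprop, ll_h
                if it < config.n_warmup:
                    eta = min(1.0, 10.0 / (it + 20))
                    step_v *= np.exp(eta * (acc.mean() - 0.35))
                if it >= config.n_warmup and \
                        (it - config.n_warmup + 1) % config.thinning == 0:
                    a, b, se, sc = np.exp(hyp)
                    keep["omega_a"].append(a)
                    keep["omega_b"].append(b)
                    keep["sigma_enc"].append(se)
                    keep["sigma_comp"].append(sc)
                    vkeep.append(values.copy())
            chain_store.append(np.column_stack([keep[k] for k in all_draws]))
            for k in all_draws:
                all_draws[k].extend(keep[k])
            value_draws.extend(vkeep)
        chains = np.stack(chain_store)
        diag = diagnostics(chains, names=list(all_draws))
        draws = {k: np.asarray(v) for k, v in all_draws.items()}
        value_draws = np.asarray(value_draws)
        model = EncodingModel(
            (float(np.median(draws["omega_a"])),
             float(np.median(draws["omega_b"]))),
            float(np.median(draws["sigma_enc"])),
            float(np.median(draws["sigma_comp"])),
            values=np.median(value_draws, axis=0), g_map=self.g_map,
            delta_half=self.delta_half)
        return RatingModelResults(model=model, draws=draws,
                                  value_draws=value_draws,
                                  item_ids=self.item_ids, diagnostics=diag,
                                  n_items=self.M)


# ---------------------------------------------------------------------------
# Confidence-linked hierarchical choice model


@dataclass
class ECChoiceResults:
    """Posterior for the confidence-linked efficient-coding choice model."""

    draws: dict                  # population-level parameter draws
    subject_draws: dict          # per-subject slope draws
    diagnostics: object
    variant: str
    n_subjects: int

    def slope_summary(self):
        """Posterior median, s.d. and tail mass for each population slope."""
        out = {}
        for x in ("theta", "sigma_enc", "sigma_comp"):
            d = self.draws[f"beta_{x}"]
            tail = min((d > 0).mean(), (d < 0).mean())
            sd_pop = np.median(self.draws[f"sigma_{x}_pop"])
            out[x] = {"median": float(np.median(d)), "sd": float(np.std(d)),
                      "tail_prob": float(tail),
                      "effect_size": float(np.median(d) / sd_pop)}
        return out

    def summary(self) -> str:
        lines = ["Efficient-coding choice model (%s variant, %d subjects)"
                 % (self.variant, self.n_subjects),
                 "%-18s %10s %8s %10s" % ("slope", "median", "sd", "P(!=0)")]
        for x, s in self.slope_summary().items():
            lines.append("%-18s %10.4f %8.4f %10.3f"
                         % ("beta_" + x, s["median"], s["sd"],
                            1 - 2 * s["tail_prob"]))
        return "\n".join(lines)


class ECChoiceModel:
    """Hierarchical probit choice model on efficiently-coded values.

    Trial-wise parameters x_n = x_base_s + beta_s^x * c_n for
    x in {theta, sigma_enc, sigma_comp}; subject slopes and bases are drawn
    from population normals.  The item values and prior shape come from an
    out-of-sample rating fit and stay fixed here.

    Data arrays (one entry per trial): subject index, v_i/v_j (latent
    values of the chosen-side pair: v_i is the upper item), A_i dwell
    share, choice_i bool, confidence in [0, 1].
    """

    PRIOR_BOUNDS = {
        # Uniform prior bounds; normal priors on the slope means are flat
        # (precision-convention 1e-10)
        "theta_base": (-0.5, 1.5),
        "sigma_enc_base": (1e-10, 5.0),
        "sigma_comp_base": (1e-10, 5.0),
        "beta_sigma_enc": (-0.2, 0.5),
    }

    def __init__(self, subject_idx, v_i, v_j, A_i, choice_i, confidence,
                 omega, g_map: GMap | None = None, delta_half=False,
                 variant="linked"):
        self.subj = np.asarray(subject_idx, dtype=int)
        self.v_i = np.asarray(v_i, dtype=float)
        self.v_j = np.asarray(v_j, dtype=float)
        self.A_i = np.asarray(A_i, dtype=float)
        self.y = np.asarray(choice_i, dtype=bool)
        self.c = np.asarray(confidence, dtype=float)
        self.omega = omega
        self.delta_half = delta_half
        self.variant = variant
        self.S = int(self.subj.max()) + 1
        # encode once: moments depend only on fixed values/omega
        self.e_i, base_var_i = encode_moments(self.v_i, 1.0, omega,
                                              delta_half=delta_half)
        self.e_j, base_var_j = encode_moments(self.v_j, 1.0, omega,
                                              delta_half=delta_half)
        # note: bias term scales with sigma_enc^2, variance with sigma_enc^2;
        # store unit-noise pieces and rescale per draw
        self.phi2_i = self.e_i - self.v_i
        self.phi2_j = self.e_j - self.v_j
        self.phi1sq_i = base_var_i
        self.phi1sq_j = base_var_j

    def _trial_loglik(self, theta_n, s_enc_n, s_comp_n):
        bad = (s_enc_n < 0) | (s_comp_n <= 0)
        s_enc2 = np.where(bad, np.nan, s_enc_n) ** 2
        e_i = self.v_i + self.phi2_i * s_enc2
        e_j = self.v_j + self.phi2_j * s_enc2
        var = (self.phi1sq_i + self.phi1sq_j) * s_enc2 + s_comp_n ** 2
        A_i = self.A_i
        A_j = 1.0 - A_i
        num = A_i * e_i - A_j * e_j + theta_n * (A_j * e_i - A_i * e_j)
        z = num / np.sqrt(var)
        ll = np.where(self.y, log_ndtr(z), log_ndtr(-z))
        return np.where(bad, -np.inf, ll)

    def _subject_loglik(self, bases, slopes):
        """bases (3,), slopes (S, 3) -> per-subject summed log-likelihood."""
        th = bases[0] + slopes[self.subj, 0] * self.c
        se = bases[1] + slopes[self.subj, 1] * self.c
        sc = bases[2] + slopes[self.subj, 2] * self.c
        ll = self._trial_loglik(th, se, sc)
        out = np.zeros(self.S)
        np.add.at(out, self.subj, ll)
        return out

    def fit(self, config: MCMCConfig | None = None) -> ECChoiceResults:
        config = config or MCMCConfig(n_warmup=800, n_keep=500)
        linked = self.variant == "linked"
        pop_names = ["theta_base", "sigma_enc_base", "sigma_comp_base",
                     "beta_theta", "beta_sigma_enc", "beta_sigma_comp",
                     "sigma_theta_pop", "sigma_sigma_enc_pop",
                     "sigma_sigma_comp_pop"]
        chain_store = []
        subj_draws = []
        for chain in range(config.n_chains):
            rng = np.random.default_rng(config.seed * 1733 + 13 * chain)
            bases = np.array([0.7, 0.05, 0.1])
            betas = np.zeros(3)          # population slope means
            sig_pop = np.full(3, 0.1)    # population slope s.d.
            slopes = np.zeros((self.S, 3))
            step_b = np.array([0.08, 0.01, 0.02])
            step_s = np.full(3, 0.05)
            ll_s = self._subject_loglik(bases, slopes)
            keep = []
            skeep = []
            total = config.n_warmup + config.n_keep * config.thinning
            for it in range(total):
                # base block (global)
                prop = bases + step_b * rng.standard_normal(3)
                if self._bases_ok(prop):
                    ll_p = self._subject_loglik(prop, slopes)
                    if np.log(rng.uniform()) < ll_p.sum() - ll_s.sum():
                        bases, ll_s = prop, ll_p
                if linked:
                    # subject slope block, one component at a time,
                    # vectorized across subjects
                    for d in range(3):
                        prop_s = slopes.copy()
                        prop_s[:, d] += step_s[d] * rng.standard_normal(self.S)
                        if d == 1:  # beta_sigma_enc has bounded support
                            lo, hi = self.PRIOR_BOUNDS["beta_sigma_enc"]
                            inside = (prop_s[:, d] > lo) & (prop_s[:, d] < hi)
                        else:
                            inside = np.ones(self.S, dtype=bool)
                        ll_p = self._subject_loglik(bases, prop_s)
                        pr_old = -0.5 * ((slopes[:, d] - betas[d])
                                         / sig_pop[d]) ** 2
                        pr_new = -0.5 * ((prop_s[:, d] - betas[d])
                                         / sig_pop[d]) ** 2
                        acc = (np.log(rng.uniform(size=self.S))
                               < ll_p - ll_s + pr_new - pr_old) & inside
                        slopes[acc, d] = prop_s[acc, d]
                        ll_s = np.where(acc, ll_p, ll_s)
                    # population conjugate updates (truncated where the
                    # prior bounds the population mean)
                    for d in range(3):
                        m = slopes[:, d].mean()
                        s_ = sig_pop[d] / np.sqrt(self.S)
                        if d == 1:
                            lo, hi = self.PRIOR_BOUNDS["beta_sigma_enc"]
                            betas[d] = float(stats.truncnorm.rvs(
                                (lo - m) / s_, (hi - m) / s_, loc=m,
                                scale=s_, random_state=rng))
                        else:
                            betas[d] = rng.normal(m, s_)
                        sig_pop[d] = _sample_sigma(slopes[:, d] - betas[d],
                                                   rng, upper=5.0)
                if it < config.n_warmup and it % 25 == 24:
                    pass
                if it >= config.n_warmup and \
                        (it - config.n_warmup + 1) % config.thinning == 0:
                    keep.append(np.concatenate([bases, betas, sig_pop]))
                    skeep.append(slopes.copy())
            chain_store.append(np.asarray(keep))
            subj_draws.append(np.asarray(skeep))
        chains = np.stack(chain_store)
        diag = diagnostics(chains, names=pop_names)
        flat = chains.reshape(-1, chains.shape[-1])
        draws = {n: flat[:, i] for i, n in enumerate(pop_names)}
        sd = np.concatenate(subj_draws, axis=0)
        subject_draws = {"beta_theta": sd[:, :, 0],
                         "beta_sigma_enc": sd[:, :, 1],
                         "beta_sigma_comp": sd[:, :, 2]}
        return ECChoiceResults(draws=draws, subject_draws=subject_draws,
                               diagnostics=diag, variant=self.variant,
                               n_subjects=self.S)

    def _bases_ok(self, bases):
        b = self.PRIOR_BOUNDS
        return (b["theta_base"][0] < bases[0] < b["theta_base"][1]
                and b["sigma_enc_base"][0] < bases[1] < b["sigma_enc_base"][1]
                and b["sigma_comp_base"][0] < bases[2] < b["sigma_comp_base"][1])


def _sample_sigma(resid, rng, upper=5.0, lower=1e-3, n_grid=120):
    """Draw a population s.d. from its conditional under a uniform prior,
    by discretizing the conditional on a log grid."""
    n = resid.size
    ss = np.sum(resid ** 2)
    grid = np.exp(np.linspace(np.log(lower), np.log(upper), n_grid))
    logp = -n * np.log(grid) - ss / (2 * grid ** 2) + np.log(grid)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(rng.choice(grid, p=p))
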