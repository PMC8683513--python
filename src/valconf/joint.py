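"""Joint ("covariance") modeling of confidence and race-model latents.

Trial-wise confidence c_n, attentional effort theta_n and evidence gain
k_n are treated as draws from a common trivariate normal linking
distribution with mean (mu_c, mu_theta, mu_k) and covariance built from
(sigma_c, sigma_theta, sigma_k) and correlations (rho_ctheta, rho_ck,
rho_ktheta).  The nine hyperparameters are sampled jointly with the
per-trial latents under the race likelihood of (choice, RT); the
correlations quantify the trial-to-trial coupling between confidence and
the decision process.

Priors follow the uninformative scheme of the original analysis: flat
normals on the means (the Normal(0, 1e-5) notation is read in the
precision convention - the variance reading would be strongly
informative and contradict "uninformative"), Uniform(0, 10) on the
standard deviations and Uniform(-1, 1) on the correlations.  The sampler
interweaves non-centered updates (standard-normal latent residuals, so
the race likelihood informs the correlations directly) with centered
updates of the linking parameters given the current latents; the
combination avoids the funnel degeneracies either parameterization is
prone to on its own.

Confidence predictions for the four model variants are produced by
plugging fixed (F) subject-level or variable (V) trial-level parameters
into the heuristic (H) or normative (N) confidence generators, linearly
rescaled onto the observed confidence scale; variants are compared by
PSIS-LOO and bridge-sampling Bayes factors of the rescaling regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

from .confidence import NormativePredictor, expected_heuristic_confidence
from .engine import MCMCConfig, diagnostics, log_marginal_bridge, loo
from .glam import GLAMModel, GLAMParams, drift_terms, race_loglik

__all__ = ["JointHyper", "TrialLatents", "JointModel", "JointResults",
           "infer_trialwise", "predict_confidence", "rescale_predictions",
           "compare_models", "VARIANTS"]

VARIANTS = ("FH", "VH", "FN", "VN")


@dataclass(frozen=True)
class JointHyper:
    """Hyperparameters of the (c, theta, k) linking distribution.

    rho is ordered (rho_ctheta, rho_ck, rho_ktheta).
    """

    mu: tuple
    sigma: tuple
    rho: tuple

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma):
            raise ValueError("linking standard deviations must be positive")
        if any(abs(r) >= 1 for r in self.rho):
            raise ValueError("correlations must lie in (-1, 1)")
        c = self.cov()
        if np.min(np.linalg.eigvalsh(c)) <= 0:
            raise ValueError("implied covariance is not positive definite")

    def cov(self) -> np.ndarray:
        sc, st, sk = self.sigma
        r_ct, r_ck, r_kt = self.rho
        return np.array([
            [sc * sc, r_ct * sc * st, r_ck * sc * sk],
            [r_ct * sc * st, st * st, r_kt * sk * st],
            [r_ck * sc * sk, r_kt * sk * st, sk * sk]])

    @classmethod
    def from_cov(cls, mu, cov) -> "JointHyper":
        cov = np.asarray(cov, dtype=float)
        s = np.sqrt(np.diag(cov))
        return cls(mu=tuple(np.asarray(mu, float)), sigma=tuple(s),
                   rho=(cov[0, 1] / (s[0] * s[1]),
                        cov[0, 2] / (s[0] * s[2]),
                        cov[1, 2] / (s[1] * s[2])))

    def conditional_theta_k(self, c):
        """Conditional mean (n, 2) and covariance (2, 2) of (theta, k) | c."""
        cov = self.cov()
        c = np.atleast_1d(np.asarray(c, dtype=float))
        s12 = cov[1:, 0]
        mean = np.asarray(self.mu[1:]) + np.outer(
            (c - self.mu[0]) / cov[0, 0], s12)
        ccov = cov[1:, 1:] - np.outer(s12, s12) / cov[0, 0]
        return mean, ccov


@dataclass
class TrialLatents:
    """Per-trial (theta_n, k_n): posterior draws and summaries."""

    theta_draws: np.ndarray    # (n_draws, n_trials)
    k_draws: np.ndarray

    @property
    def theta_mean(self):
        return self.theta_draws.mean(axis=0)

    @property
    def k_mean(self):
        return self.k_draws.mean(axis=0)


HYPER_NAMES = ["mu_c", "mu_theta", "mu_k", "sigma_c", "sigma_theta",
               "sigma_k", "rho_ctheta", "rho_ck", "rho_ktheta"]


@dataclass
class JointResults:
    hyper_draws: dict            # name -> (n_draws,)
    latents: TrialLatents
    glam_params: GLAMParams      # posterior-median plug-in (B = 1)
    glam_draws: dict             # sigma, tau draws
    diagnostics: object
    config: MCMCConfig
    mode: str

    def hyper_median(self) -> JointHyper:
        m = {k: float(np.median(v)) for k, v in self.hyper_draws.items()}
        return JointHyper(mu=(m["mu_c"], m["mu_theta"], m["mu_k"]),
                          sigma=(m["sigma_c"], m["sigma_theta"], m["sigma_k"]),
                          rho=(m["rho_ctheta"], m["rho_ck"], m["rho_ktheta"]))

    def rho_interval(self, name, level=0.95):
        d = self.hyper_draws[name]
        a = (1 - level) / 2
        return tuple(np.quantile(d, [a, 1 - a]))

    def summary(self) -> str:
        lines = ["Joint covariance model (%s mode)" % self.mode,
                 "%-12s %10s %18s" % ("param", "median", "95% interval")]
        for n in HYPER_NAMES:
            d = self.hyper_draws[n]
            lo, hi = np.quantile(d, [0.025, 0.975])
            lines.append("%-12s %10.3f    [%7.3f, %7.3f]"
                         % (n, np.median(d), lo, hi))
        return "\n".join(lines)


class JointModel:
    """Joint sampler for one subject's trials.

    Parameters
    ----------
    rts, choices_upper, v_up, v_low, g_up, confidence : per-trial arrays.
    mode : "joint" samples (sigma, tau) of the race inside the chain;
        "cut" freezes them at a first-stage MAP fit (two-stage estimation).
    """

    def __init__(self, rts, choices_upper, v_up, v_low, g_up, confidence,
                 subject_idx=None, mode="joint"):
        self.rts = np.asarray(rts, dtype=float)
        self.choices_upper = np.asarray(choices_upper, dtype=bool)
        self.v_up = np.asarray(v_up, dtype=float)
        self.v_low = np.asarray(v_low, dtype=float)
        self.g_up = np.asarray(g_up, dtype=float)
        self.c = np.asarray(confidence, dtype=float)
        self.n = self.rts.size
        if subject_idx is None:
            subject_idx = np.zeros(self.n, dtype=int)
        self.subj = np.asarray(subject_idx, dtype=int)
        self.S = int(self.subj.max()) + 1
        self.mode = mode

    @classmethod
    def from_dataset(cls, ds, **kw):
        tr = ds.valid_trials()
        return cls(rts=[t.rt_s for t in tr],
                   choices_upper=[t.choice == "upper" for t in tr],
                   v_up=[t.v_upper for t in tr], v_low=[t.v_lower for t in tr],
                   g_up=[t.g_upper for t in tr],
                   confidence=[t.confidence for t in tr], **kw)

    @classmethod
    def from_population(cls, datasets, **kw):
        """Pooled model across subjects: the linking means, spreads and
        correlations are shared; confidence location/scale is per subject
        (rating-scale use differs between sessions)."""
        cols = {k: [] for k in ("rts", "ch", "vu", "vl", "g", "c", "s")}
        for s, ds in enumerate(datasets):
            for t in ds.valid_trials():
                cols["rts"].append(t.rt_s)
                cols["ch"].append(t.choice == "upper")
                cols["vu"].append(t.v_upper)
                cols["vl"].append(t.v_lower)
                cols["g"].append(t.g_upper)
                cols["c"].append(t.confidence)
                cols["s"].append(s)
        return cls(rts=cols["rts"], choices_upper=cols["ch"], v_up=cols["vu"],
                   v_low=cols["vl"], g_up=cols["g"], confidence=cols["c"],
                   subject_idx=cols["s"], **kw)

    def _glam_ll(self, sigma, tau, theta_n, k_n):
        p = GLAMParams(k=1.0, sigma=sigma, tau=tau, theta=0.0)
        return race_loglik(self.rts, self.choices_upper, self.v_up,
                           self.v_low, self.g_up, p, theta=theta_n, k=k_n)

    # hyper vector layout: [mu_c (S), log sigma_c (S),
    #                       mu_theta, mu_k, log s_theta, log s_k,
    #                       atanh rho_ctheta, atanh rho_ck, atanh rho_ktheta]
    def _hyper_natural(self, h):
        S = self.S
        mu_c = h[:S]
        sig_c = np.exp(h[S:2 * S])
        mu_tk = h[2 * S:2 * S + 2]
        sig_tk = np.exp(h[2 * S + 2:2 * S + 4])
        rho = np.tanh(h[2 * S + 4:2 * S + 7])
        return mu_c, sig_c, mu_tk, sig_tk, rho

    def _latents_from(self, h, eta):
        """Implied (theta_n, k_n) in the non-centered parameterization:
        conditional mean given c_n plus Cholesky(conditional covariance)
        applied to the standard-normal residuals eta."""
        mu_c, sig_c, mu_tk, sig_tk, rho = self._hyper_natural(h)
        r_ct, r_ck, r_kt = rho
        zc = (self.c - mu_c[self.subj]) / sig_c[self.subj]
        m_t = mu_tk[0] + sig_tk[0] * r_ct * zc
        m_k = mu_tk[1] + sig_tk[1] * r_ck * zc
        v_t = sig_tk[0] ** 2 * (1 - r_ct ** 2)
        v_k = sig_tk[1] ** 2 * (1 - r_ck ** 2)
        cv = sig_tk[0] * sig_tk[1] * (r_kt - r_ct * r_ck)
        l11 = np.sqrt(max(v_t, 1e-12))
        l21 = cv / l11
        l22 = np.sqrt(max(v_k - l21 ** 2, 1e-12))
        theta_n = m_t + l11 * eta[:, 0]
        k_n = m_k + l21 * eta[:, 0] + l22 * eta[:, 1]
        return theta_n, k_n

    def _hyper_logprior(self, h):
        mu_c, sig_c, mu_tk, sig_tk, rho = self._hyper_natural(h)
        if np.any(sig_c > 10) or np.any(sig_tk > 10) \
                or np.any(np.abs(mu_c) > 50) or np.any(np.abs(mu_tk) > 50):
            return -np.inf
        # rho must leave the implied 3x3 covariance positive definite
        r_ct, r_ck, r_kt = rho
        if 1 - r_ct ** 2 - r_ck ** 2 - r_kt ** 2 + 2 * r_ct * r_ck * r_kt <= 0:
            return -np.inf
        # flat on means; Uniform(0, 10) on sigmas (log transform Jacobian);
        # Uniform(-1, 1) on rhos (atanh transform Jacobian 1 - rho^2)
        S = self.S
        return float(np.sum(h[S:2 * S]) + np.sum(h[2 * S + 2:2 * S + 4])
                     + np.sum(np.log1p(-rho ** 2)))

    def _c_loglik(self, h):
        mu_c, sig_c, *_ = self._hyper_natural(h)
        resid = (self.c - mu_c[self.subj]) / sig_c[self.subj]
        return float(-np.sum(np.log(sig_c[self.subj]))
                     - 0.5 * np.sum(resid ** 2))

    def _rows_loglik(self, h, theta_n, k_n):
        """Trivariate-normal log density of the (c, theta, k) rows."""
        mu_c, sig_c, mu_tk, sig_tk, rho = self._hyper_natural(h)
        r_ct, r_ck, r_kt = rho
        corr = np.array([[1.0, r_ct, r_ck], [r_ct, 1.0, r_kt],
                         [r_ck, r_kt, 1.0]])
        try:
            lc = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            return -np.inf
        z = np.column_stack([
            (self.c - mu_c[self.subj]) / sig_c[self.subj],
            (theta_n - mu_tk[0]) / sig_tk[0],
            (k_n - mu_tk[1]) / sig_tk[1]])
        w = np.linalg.solve(lc, z.T)
        logdet_corr = 2.0 * np.sum(np.log(np.diag(lc)))
        logdet_scales = (np.sum(np.log(sig_c[self.subj]))
                         + self.n * np.sum(np.log(sig_tk)))
        return float(-0.5 * np.sum(w * w) - 0.5 * self.n * logdet_corr
                     - logdet_scales)

    def _eta_from(self, h, theta_n, k_n):
        """Invert the non-centered map: residuals implied by latents."""
        mu_c, sig_c, mu_tk, sig_tk, rho = self._hyper_natural(h)
        r_ct, r_ck, r_kt = rho
        zc = (self.c - mu_c[self.subj]) / sig_c[self.subj]
        m_t = mu_tk[0] + sig_tk[0] * r_ct * zc
        m_k = mu_tk[1] + sig_tk[1] * r_ck * zc
        v_t = sig_tk[0] ** 2 * (1 - r_ct ** 2)
        v_k = sig_tk[1] ** 2 * (1 - r_ck ** 2)
        cv = sig_tk[0] * sig_tk[1] * (r_kt - r_ct * r_ck)
        l11 = np.sqrt(max(v_t, 1e-12))
        l21 = cv / l11
        l22 = np.sqrt(max(v_k - l21 ** 2, 1e-12))
        e1 = (theta_n - m_t) / l11
        e2 = (k_n - m_k - l21 * e1) / l22
        return np.column_stack([e1, e2])

    def fit(self, config: MCMCConfig | None = None,
            start: GLAMParams | None = None) -> JointResults:
        config = config or MCMCConfig(n_warmup=600, n_keep=400)
        if start is None:
            start = GLAMModel(self.rts, self.choices_upper, self.v_up,
                              self.v_low, self.g_up).fit(n_restarts=2).params
        n, S = self.n, self.S
        ndim = 2 * S + 7
        c_mean = np.array([self.c[self.subj == s].mean() for s in range(S)])
        c_sd = np.array([max(self.c[self.subj == s].std(), 1e-3)
                         for s in range(S)])
        h0 = np.concatenate([c_mean, np.log(c_sd),
                             [start.theta, start.k, np.log(0.1),
                              np.log(0.1 * start.k), 0.0, 0.0, 0.0]])
        hyper_store, latent_store_t, latent_store_k, glam_store = [], [], [], []
        for chain in range(config.n_chains):
            rng = np.random.default_rng(config.seed * 3301 + 17 * chain)
            sigma, tau = start.sigma, start.tau
            h = h0 + 0.02 * rng.standard_normal(ndim)
            eta = rng.standard_normal((n, 2))
            theta_n, k_n = self._latents_from(h, eta)
            ll = self._glam_ll(sigma, tau, theta_n, k_n)
            lp_h = self._c_loglik(h) + self._hyper_logprior(h)
            log_s = np.log(0.05)
            log_s_cs = 0.0
            hmean = h[2 * S:].copy()
            hm2 = np.zeros((7, 7))
            hchol = np.eye(7)
            n_seen = 1
            log_s_c = np.log(0.05)      # centered-block proposal scale
            cchol = np.eye(7)
            cmean = h[2 * S:].copy()
            cm2 = np.zeros((7, 7))
            c_seen = 1
            step_gl = np.array([0.08, 0.15])
            total = config.n_warmup + config.n_keep * config.thinning
            keep_h, keep_t, keep_k, keep_g = [], [], [], []
            for it in range(total):
                # --- residual block: eta ~ N(0, I) independence proposals;
                # the prior cancels, acceptance is the race-likelihood
                # ratio per trial (vectorized) ----------------------------
                prop_eta = rng.standard_normal((n, 2))
                pt, pk = self._latents_from(h, prop_eta)
                ok = pk > 1e-3
                pt = np.where(ok, pt, theta_n)
                pk = np.where(ok, pk, k_n)
                ll_prop = self._glam_ll(sigma, tau, pt, pk)
                acc = (np.log(rng.uniform(size=n)) < ll_prop - ll) & ok
                eta[acc] = prop_eta[acc]
                theta_n = np.where(acc, pt, theta_n)
                k_n = np.where(acc, pk, k_n)
                ll = np.where(acc, ll_prop, ll)
                # --- hyper block: adaptive MH on the transformed scale,
                # residuals held fixed (non-centered), so the race
                # likelihood informs the correlations directly.  Split into
                # a shared-linking block (moved often: the correlations mix
                # slowly) and a per-subject confidence-scale block. -------
                for lo_idx, width, n_prop, state in (
                        (2 * S, 7, 5, "shared"), (0, 2 * S, 2, "cscale")):
                    for _ in range(n_prop):
                        prop_h = h.copy()
                        if state == "shared":
                            step = np.exp(log_s) * (
                                hchol @ rng.standard_normal(width))
                        else:
                            step = np.exp(log_s_cs) * rng.standard_normal(width) * 0.05
                        prop_h[lo_idx:lo_idx + width] += step
                        lp_prop = (self._c_loglik(prop_h)
                                   + self._hyper_logprior(prop_h))
                        accepted = 0.0
                        if np.isfinite(lp_prop):
                            pt, pk = self._latents_from(prop_h, eta)
                            if np.all(pk > 1e-3):
                                ll_p = self._glam_ll(sigma, tau, pt, pk)
                                a = ll_p.sum() + lp_prop - ll.sum() - lp_h
                                if np.log(rng.uniform()) < a:
                                    h, lp_h = prop_h, lp_prop
                                    theta_n, k_n, ll = pt, pk, ll_p
                                    accepted = 1.0
                        if it < config.n_warmup:
                            etaa = min(1.0, 5.0 / (it + 10))
                            if state == "shared":
                                log_s += etaa * (accepted - 0.27)
                                n_seen += 1
                                delta = h[2 * S:] - hmean
                                hmean += delta / n_seen
                                hm2 += np.outer(delta, h[2 * S:] - hmean)
                                if n_seen > 100 and n_seen % 50 == 0:
                                    c_est = hm2 / (n_seen - 1) \
                                        + 1e-9 * np.eye(7)
                                    try:
                                        hchol = np.linalg.cholesky(c_est)
                                    except np.linalg.LinAlgError:
                                        pass
                            else:
                                log_s_cs += etaa * (accepted - 0.27)
                # --- centered block (interweaving): with the latents held
                # fixed as data rows, MH on the shared linking parameters
                # under the trivariate-normal row likelihood; eta is then
                # re-derived.  Alternating centered and non-centered
                # updates sidesteps the funnel either parameterization
                # hits alone. --------------------------------------------
                lr = self._rows_loglik(h, theta_n, k_n) + self._hyper_logprior(h)
                for _ in range(6):
                    prop_h = h.copy()
                    prop_h[2 * S:] = (h[2 * S:] + np.exp(log_s_c)
                                      * (cchol @ rng.standard_normal(7)))
                    lp_pr = self._hyper_logprior(prop_h)
                    accepted_c = 0.0
                    if np.isfinite(lp_pr):
                        lr_p = self._rows_loglik(prop_h, theta_n, k_n) + lp_pr
                        if np.log(rng.uniform()) < lr_p - lr:
                            h, lr = prop_h, lr_p
                            accepted_c = 1.0
                    if it < config.n_warmup:
                        etaa = min(1.0, 5.0 / (it + 10))
                        log_s_c += etaa * (accepted_c - 0.27)
                        c_seen += 1
                        delta = h[2 * S:] - cmean
                        cmean += delta / c_seen
                        cm2 += np.outer(delta, h[2 * S:] - cmean)
                        if c_seen > 100 and c_seen % 50 == 0:
                            c_est = cm2 / (c_seen - 1) + 1e-9 * np.eye(7)
                            try:
                                cchol = np.linalg.cholesky(c_est)
                            except np.linalg.LinAlgError:
                                pass
                eta = self._eta_from(h, theta_n, k_n)
                lp_h = self._c_loglik(h) + self._hyper_logprior(h)
                # --- (sigma, tau) race-noise block -----------------------
                if self.mode == "joint":
                    prop = np.array([sigma, tau]) * np.exp(
                        step_gl * rng.standard_normal(2))
                    if 1e-3 < prop[0] < 50 and 1e-3 < prop[1] < 500:
                        ll_g = self._glam_ll(prop[0], prop[1], theta_n, k_n)
                        jac = np.log(prop[0] * prop[1]) - np.log(sigma * tau)
                        if np.log(rng.uniform()) < ll_g.sum() - ll.sum() + jac:
                            sigma, tau = prop
                            ll = ll_g
                if it >= config.n_warmup and \
                        (it - config.n_warmup + 1) % config.thinning == 0:
                    mu_c, sig_c, mu_tk, sig_tk, rho = self._hyper_natural(h)
                    keep_h.append([mu_c.mean(), mu_tk[0], mu_tk[1],
                                   sig_c.mean(), sig_tk[0], sig_tk[1],
                                   rho[0], rho[1], rho[2]])
                    keep_t.append(theta_n.copy())
                    keep_k.append(k_n.copy())
                    keep_g.append([sigma, tau])
            hyper_store.append(np.asarray(keep_h))
            latent_store_t.append(np.asarray(keep_t))
            latent_store_k.append(np.asarray(keep_k))
            glam_store.append(np.asarray(keep_g))
        chains = np.stack(hyper_store)
        diag = diagnostics(chains, names=HYPER_NAMES)
        flat = chains.reshape(-1, 9)
        hyper_draws = {nme: flat[:, i] for i, nme in enumerate(HYPER_NAMES)}
        gl = np.concatenate(glam_store, axis=0)
        glam_draws = {"sigma": gl[:, 0], "tau": gl[:, 1]}
        latents = TrialLatents(
            theta_draws=np.concatenate(latent_store_t, axis=0),
            k_draws=np.concatenate(latent_store_k, axis=0))
        params = GLAMParams(
            k=float(np.median(hyper_draws["mu_k"])),
            sigma=float(np.median(glam_draws["sigma"])),
            tau=float(np.median(glam_draws["tau"])),
            theta=float(np.median(hyper_draws["mu_theta"])))
        return JointResults(hyper_draws=hyper_draws, latents=latents,
                            glam_params=params, glam_draws=glam_draws,
                            diagnostics=diag, config=config, mode=self.mode)


def infer_trialwise(hyper: JointHyper, confidence, n_draws=200,
                    rng=None) -> TrialLatents:
    """Conditional-normal draws of (theta_n, k_n) given observed confidence."""
    rng = np.random.default_rng(rng)
    mean, ccov = hyper.conditional_theta_k(confidence)
    chol = np.linalg.cholesky(ccov)
    z = rng.standard_normal((n_draws, mean.shape[0], 2))
    draws = mean[None] + z @ chol.T
    return TrialLatents(theta_draws=draws[:, :, 0], k_draws=draws[:, :, 1])


def predict_confidence(variant, rts, choices_upper, v_up, v_low, g_up,
                       results: JointResults, confidence=None,
                       predictor: NormativePredictor | None = None,
                       n_sim=15_000, seed=0):
    """Raw per-trial confidence predictions for one model variant.

    FH/FN use the subject-level plug-in parameters; VH/VN use the
    conditional posterior means of the trial latents given the observed
    confidence (which therefore must be supplied for V variants).
    Heuristic variants evaluate the expected balance of evidence at the
    observed RT; normative variants marginalize the loser evidence with a
    simulation-based context table.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    rts = np.asarray(rts, dtype=float)
    choices_upper = np.asarray(choices_upper, dtype=bool)
    v_up = np.asarray(v_up, dtype=float)
    v_low = np.asarray(v_low, dtype=float)
    g_up = np.asarray(g_up, dtype=float)
    params = results.glam_params
    if variant[0] == "V":
        if confidence is None:
            raise ValueError("V variants need the observed confidence")
        hyper = results.hyper_median()
        mean, _ = hyper.conditional_theta_k(np.asarray(confidence, float))
        theta_n, k_n = mean[:, 0], np.maximum(mean[:, 1], 1e-3)
    else:
        theta_n = np.full(rts.size, params.theta)
        k_n = np.full(rts.size, params.k)
    if variant[1] == "H":
        r_up, r_low = drift_terms(v_up, v_low, g_up, params, theta=theta_n)
        r_loser = np.where(choices_upper, r_low, r_up)
        return expected_heuristic_confidence(rts, r_loser, params, k=k_n)
    # normative variants
    cls = np.where(choices_upper, v_up >= v_low, v_low >= v_up)
    if predictor is None:
        contexts = np.column_stack([v_up, v_low, g_up])
        predictor = NormativePredictor(contexts, params, n_sim=n_sim,
                                       seed=seed)
    return predictor.predict(cls, rts, v_up, v_low, g_up, theta=theta_n,
                             k=k_n)


def rescale_predictions(pred_raw, confidence_observed):
    """OLS affine map of raw predictions onto the observed confidence scale.

    Returns (rescaled predictions, slope, intercept).  Zero-variance raw
    predictions cannot be rescaled and are flagged degenerate.
    """
    x = np.asarray(pred_raw, dtype=float)
    y = np.asarray(confidence_observed, dtype=float)
    if x.size < 2 or np.var(x) == 0:
        warnings.warn("degenerate rescaling: raw predictions have zero variance")
        return np.full_like(y, y.mean()), 0.0, float(y.mean())
    slope, intercept = np.polyfit(x, y, 1)
    return intercept + slope * x, float(slope), float(intercept)


def _conjugate_regression_draws(x, y, n_draws=800, rng=None):
    """Posterior draws and pointwise log-likelihood for y ~ a + b x + eps.

    Conjugate normal-inverse-gamma with a vague prior; returns
    (draws (n_draws, 3) of (a, b, log sigma), loglik (n_draws, n))
    plus the unnormalized log-posterior callable (for bridge sampling).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    # vague NIG prior: V0^-1 = tau0 I, a0, b0 small
    tau0, a0, b0 = 1e-4, 0.01, 0.01
    Vn_inv = tau0 * np.eye(2) + X.T @ X
    Vn = np.linalg.inv(Vn_inv)
    beta_n = Vn @ (X.T @ y)
    a_n = a0 + n / 2
    b_n = b0 + 0.5 * (y @ y - beta_n @ Vn_inv @ beta_n)
    sig2 = stats.invgamma.rvs(a_n, scale=b_n, size=n_draws, random_state=rng)
    z = rng.standard_normal((n_draws, 2))
    chol = np.linalg.cholesky(Vn)
    betas = beta_n[None] + np.sqrt(sig2)[:, None] * (z @ chol.T)
    resid = y[None, :] - betas @ X.T
    ll = (-0.5 * np.log(2 * np.pi * sig2)[:, None]
          - 0.5 * resid ** 2 / sig2[:, None])
    draws = np.column_stack([betas, 0.5 * np.log(sig2)])

    def log_target(par):
        a, b_, logs = par
        s2 = np.exp(2 * logs)
        r = y - a - b_ * x
        llv = -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * np.sum(r * r) / s2
        lp = (stats.norm.logpdf(a, 0, 1 / np.sqrt(tau0))
              + stats.norm.logpdf(b_, 0, 1 / np.sqrt(tau0))
              + stats.invgamma.logpdf(s2, a0, scale=b0)
              + np.log(2 * s2))  # Jacobian d(sigma^2)/d(log sigma)
        return llv + lp

    return draws, ll, log_target


def compare_models(predictions: dict, confidence, n_draws=800, seed=0,
                   compute_bf=True) -> pd.DataFrame:
    """LOO and Bayes-factor comparison of confidence-prediction variants.

    predictions : mapping variant name -> raw predictions.  Each variant
    is scored through the linear rescaling regression of observed
    confidence on its raw predictions (PSIS-LOO of the pointwise
    likelihood; pairwise BF vs. the best model by bridge sampling).
    """
    y = np.asarray(confidence, dtype=float)
    rows = {}
    loos = {}
    bridge = {}
    for name, pred in predictions.items():
        draws, ll, log_target = _conjugate_regression_draws(
            np.asarray(pred, float), y, n_draws=n_draws, rng=seed)
        res = loo(ll)
        loos[name] = res
        if compute_bf:
            lm, _ = log_marginal_bridge(draws, log_target, rng=seed + 1)
            bridge[name] = lm
        rows[name] = res.elpd
    best = max(rows, key=rows.get)
    out = []
    for name in predictions:
        entry = {"model": name, "elpd_loo": loos[name].elpd,
                 "se": loos[name].se,
                 "d_elpd": loos[name].elpd - loos[best].elpd,
                 "loo_unreliable": loos[name].unreliable}
        if compute_bf:
            entry["log_bf_vs_best"] = bridge[name] - bridge[best]
        out.append(entry)
    df = pd.DataFrame(out).sort_values("elpd_loo", ascending=False)
    return df.reset_index(drop=True)
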