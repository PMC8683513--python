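"""Static random-utility choice models with attentional weighting.

The baseline model is a probit on the value difference,
``P(i over j) = Phi((v_i - v_j) / (sigma sqrt(2)))``.  The attentional
variant weights each item by the fraction of dwell time A_i it received,
with the non-attended component discounted by the attentional effort
theta:

    P(i over j) = Phi((A_i v_i - A_j v_j + theta (A_j v_i - A_i v_j))
                      / (sigma sqrt(2)))

At theta = 1 the attentional model reduces exactly to the baseline.
Confidence enters as an observed covariate of the latent parameters
("reverse inference"): theta_n = theta_base + beta_s^theta c_n and
k_n = k_base + beta_s^k c_n where k = 1/(sigma sqrt(2)) is the probit
slope, with subject-specific slopes beta_s drawn from population normals.
Priors are the uninformative scheme of the original analysis (flat
normals on location parameters - precision convention - and
Uniform(1e-10, 5) on population spreads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

from .engine import MCMCConfig, diagnostics, loo

__all__ = ["rum_choice_prob", "attentional_rum_choice_prob",
           "link_parameters", "RUMParams", "RUMModel", "RUMResults"]


def rum_choice_prob(v_i, v_j, sigma, log=False):
    """Baseline probit choice probability P(v_i > v_j)."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    z = (np.asarray(v_i, float) - np.asarray(v_j, float)) / (sigma * np.sqrt(2))
    return log_ndtr(z) if log else ndtr(z)


def attentional_rum_choice_prob(v_i, v_j, A_i, theta, sigma, log=False):
    """Attention-weighted probit choice probability.

    A_i is the dwell share on item i (A_j = 1 - A_i); theta <= 1 discounts
    the non-attended value component.  Evaluated through log-Phi for
    stability at extreme arguments.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    A_i = np.asarray(A_i, dtype=float)
    if np.any((A_i < 0) | (A_i > 1)):
        raise ValueError("dwell shares must lie in [0, 1]")
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    A_j = 1.0 - A_i
    num = A_i * v_i - A_j * v_j + theta * (A_j * v_i - A_i * v_j)
    z = num / (sigma * np.sqrt(2))
    return log_ndtr(z) if log else ndtr(z)


def link_parameters(c_n, theta_base, beta_theta, k_base, beta_k):
    """Trial-wise (theta_n, k_n) from confidence through the linear links.

    k is the probit slope 1/(sigma sqrt(2)); k_n <= 0 yields an invalid
    parameterization and is rejected at the likelihood level (the linear
    link itself is returned unclipped).
    """
    c_n = np.asarray(c_n, dtype=float)
    return theta_base + beta_theta * c_n, k_base + beta_k * c_n


def _attentional_logprob_k(v_i, v_j, A_i, theta_n, k_n, chose_i):
    """Bernoulli log-likelihood with probit slope k = 1/(sigma sqrt(2))."""
    A_j = 1.0 - A_i
    num = A_i * v_i - A_j * v_j + theta_n * (A_j * v_i - A_i * v_j)
    z = k_n * num
    ll = np.where(chose_i, log_ndtr(z), log_ndtr(-z))
    return np.where(k_n > 0, ll, -np.inf)


@dataclass
class RUMParams:
    theta_base: float
    k_base: float
    beta_theta_pop: float = 0.0
    sigma_theta_pop: float = 0.0
    beta_k_pop: float = 0.0
    sigma_k_pop: float = 0.0


@dataclass
class RUMResults:
    """Posterior for the (confidence-linked) attentional random-utility model."""

    draws: dict
    subject_draws: dict | None
    diagnostics: object
    variant: str
    n_subjects: int
    loo: object | None = None

    def params_median(self) -> RUMParams:
        d = self.draws
        out = RUMParams(theta_base=float(np.median(d["theta_base"])),
                        k_base=float(np.median(d["k_base"])))
        if self.variant == "linked":
            out.beta_theta_pop = float(np.median(d["beta_theta"]))
            out.sigma_theta_pop = float(np.median(d["sigma_theta"]))
            out.beta_k_pop = float(np.median(d["beta_k"]))
            out.sigma_k_pop = float(np.median(d["sigma_k"]))
        return out

    def effect_sizes(self):
        """Population slope / population s.d., per linked parameter."""
        if self.variant != "linked":
            return {}
        return {x: float(np.median(self.draws[f"beta_{x}"])
                         / np.median(self.draws[f"sigma_{x}"]))
                for x in ("theta", "k")}

    def summary(self) -> str:
        lines = ["Attentional RUM (%s variant, %d subjects)"
                 % (self.variant, self.n_subjects),
                 "%-14s %10s %18s" % ("param", "median", "95% interval")]
        for n, d in self.draws.items():
            lo, hi = np.quantile(d, [0.025, 0.975])
            lines.append("%-14s %10.3f    [%7.3f, %7.3f]"
                         % (n, np.median(d), lo, hi))
        return "\n".join(lines)


class RUMModel:
    """Hierarchical Bernoulli-probit model of choices given values and gaze.

    Data arrays, one entry per trial: subject index, v_i / v_j (the upper
    and lower item's value), dwell share A_i on the upper item, a boolean
    for choosing the upper item, and (for the linked variant) confidence.

    variant : "fixed" shares (theta, k) across trials; "linked" adds the
        confidence covariate with subject-specific slopes drawn from
        population normals.
    """

    PRIOR_SIGMA_BOUNDS = (1e-10, 5.0)

    def __init__(self, subject_idx, v_i, v_j, A_i, chose_i, confidence=None,
                 variant="linked"):
        self.subj = np.asarray(subject_idx, dtype=int)
        self.v_i = np.asarray(v_i, dtype=float)
        self.v_j = np.asarray(v_j, dtype=float)
        self.A_i = np.asarray(A_i, dtype=float)
        self.y = np.asarray(chose_i, dtype=bool)
        self.S = int(self.subj.max()) + 1
        self.variant = variant
        if variant == "linked":
            if confidence is None:
                raise ValueError("linked variant requires confidence reports")
            self.c = np.asarray(confidence, dtype=float)
        else:
            self.c = np.zeros_like(self.v_i)
        rate = self.y.mean()
        if rate in (0.0, 1.0):
            warnings.warn("complete separation: all choices on one side; "
                          "posterior will be prior-dominated")

    @classmethod
    def from_population(cls, datasets, **kw):
        cols = {k: [] for k in ("s", "vi", "vj", "a", "y", "c")}
        for s, ds in enumerate(datasets):
            for t in ds.valid_trials():
                cols["s"].append(s)
                cols["vi"].append(t.v_upper)
                cols["vj"].append(t.v_lower)
                cols["a"].append(t.g_upper)
                cols["y"].append(t.choice == "upper")
                cols["c"].append(t.confidence)
        return cls(subject_idx=cols["s"], v_i=cols["vi"], v_j=cols["vj"],
                   A_i=cols["a"], chose_i=cols["y"], confidence=cols["c"],
                   **kw)

    def _subject_ll(self, theta_base, k_base, slopes):
        """Per-subject summed log-likelihood; slopes (S, 2) = (b_theta, b_k)."""
        theta_n = theta_base + slopes[self.subj, 0] * self.c
        k_n = k_base + slopes[self.subj, 1] * self.c
        ll = _attentional_logprob_k(self.v_i, self.v_j, self.A_i,
                                    theta_n, k_n, self.y)
        out = np.zeros(self.S)
        np.add.at(out, self.subj, ll)
        return out

    def _pointwise_ll(self, theta_base, k_base, slopes):
        theta_n = theta_base + slopes[self.subj, 0] * self.c
        k_n = k_base + slopes[self.subj, 1] * self.c
        return _attentional_logprob_k(self.v_i, self.v_j, self.A_i,
                                      theta_n, k_n, self.y)

    def fit(self, config: MCMCConfig | None = None,
            compute_loo=True) -> RUMResults:
        """Metropolis-within-Gibbs: a 2-d block on (theta_base, k_base), a
        per-subject block on the confidence slopes (vectorized across
        subjects) and conjugate/grid updates of the population moments."""
        config = config or MCMCConfig(n_warmup=800, n_keep=500)
        linked = self.variant == "linked"
        names = (["theta_base", "k_base"]
                 + (["beta_theta", "sigma_theta", "beta_k", "sigma_k"]
                    if linked else []))
        chain_store, subj_store, pw_store = [], [], []
        for chain in range(config.n_chains):
            rng = np.random.default_rng(config.seed * 4099 + 29 * chain)
            base = np.array([0.7, 3.0]) + 0.05 * rng.standard_normal(2)
            betas = np.zeros(2)
            sig_pop = np.full(2, 0.3)
            slopes = np.zeros((self.S, 2))
            step_base = np.array([0.1, 0.2])
            step_slope = np.array([0.15, 0.4])
            ll_s = self._subject_ll(base[0], base[1], slopes)
            keep, skeep, pwkeep = [], [], []
            total = config.n_warmup + config.n_keep * config.thinning
            for it in range(total):
                prop = base + step_base * rng.standard_normal(2)
                lp = self._subject_ll(prop[0], prop[1], slopes)
                a = lp.sum() - ll_s.sum()
                acc_b = np.log(rng.uniform()) < a
                if acc_b:
                    base, ll_s = prop, lp
                if linked:
                    for d in range(2):
                        prop_s = slopes.copy()
                        prop_s[:, d] += step_slope[d] * rng.standard_normal(self.S)
                        lp = self._subject_ll(base[0], base[1], prop_s)
                        pr_old = -0.5 * ((slopes[:, d] - betas[d]) / sig_pop[d]) ** 2
                        pr_new = -0.5 * ((prop_s[:, d] - betas[d]) / sig_pop[d]) ** 2
                        acc = np.log(rng.uniform(size=self.S)) < lp - ll_s + pr_new - pr_old
                        slopes[acc, d] = prop_s[acc, d]
                        ll_s = np.where(acc, lp, ll_s)
                    for d in range(2):
                        betas[d] = rng.normal(slopes[:, d].mean(),
                                              sig_pop[d] / np.sqrt(self.S))
                        sig_pop[d] = _grid_sigma(slopes[:, d] - betas[d], rng,
                                                 *self.PRIOR_SIGMA_BOUNDS)
                if it < config.n_warmup:
                    eta = min(1.0, 10.0 / (it + 20))
                    step_base *= np.exp(eta * (float(acc_b) - 0.27))
                elif (it - config.n_warmup + 1) % config.thinning == 0:
                    row = list(base)
                    if linked:
                        row += [betas[0], sig_pop[0], betas[1], sig_pop[1]]
                    keep.append(row)
                    skeep.append(slopes.copy())
                    if compute_loo and len(pwkeep) < 400:
                        pwkeep.append(self._pointwise_ll(base[0], base[1],
                                                         slopes))
            chain_store.append(np.asarray(keep))
            subj_store.append(np.asarray(skeep))
            pw_store.extend(pwkeep)
        chains = np.stack(chain_store)
        diag = diagnostics(chains, names=names)
        flat = chains.reshape(-1, chains.shape[-1])
        draws = {n: flat[:, i] for i, n in enumerate(names)}
        sd = np.concatenate(subj_store, axis=0)
        subject_draws = ({"beta_theta": sd[:, :, 0], "beta_k": sd[:, :, 1]}
                         if linked else None)
        loo_res = loo(np.asarray(pw_store)) if compute_loo else None
        return RUMResults(draws=draws, subject_draws=subject_draws,
                          diagnostics=diag, variant=self.variant,
                          n_subjects=self.S, loo=loo_res)

    def predictive_curves(self, results: RUMResults, n_bins=8):
        """Posterior-predictive choice curves for the dwell-time signature.

        Returns a DataFrame of observed and predicted P(choose upper) in
        equal-count bins of the dwell-share difference, median-split by
        confidence.
        """
        import pandas as pd
        p = results.params_median()
        slopes = (np.stack([np.median(results.subject_draws["beta_theta"], axis=(0, 1)) * np.ones(self.S),
                            np.median(results.subject_draws["beta_k"], axis=(0, 1)) * np.ones(self.S)], axis=1)
                  if results.subject_draws is not None else np.zeros((self.S, 2)))
        theta_n = p.theta_base + slopes[self.subj, 0] * self.c
        k_n = np.maximum(p.k_base + slopes[self.subj, 1] * self.c, 1e-6)
        pred = np.exp(_attentional_logprob_k(self.v_i, self.v_j, self.A_i,
                                             theta_n, k_n, np.ones_like(self.y, dtype=bool)))
        dd = 2 * self.A_i - 1
        hi_conf = self.c >= np.median(self.c)
        rows = []
        for split, mask in (("high", hi_conf), ("low", ~hi_conf)):
            q = np.quantile(dd[mask], np.linspace(0, 1, n_bins + 1))
            idx = np.clip(np.searchsorted(q, dd[mask], side="right") - 1,
                          0, n_bins - 1)
            for b in range(n_bins):
                sel = idx == b
                if sel.sum() < 3:
                    continue
                rows.append({"confidence_split": split, "bin": b,
                             "dwell_diff": float(dd[mask][sel].mean()),
                             "p_choose_upper": float(self.y[mask][sel].mean()),
                             "p_predicted": float(pred[mask][sel].mean()),
                             "n": int(sel.sum())})
        return pd.DataFrame(rows)


def _grid_sigma(resid, rng, lower=1e-10, upper=5.0, n_grid=120):
    """Population s.d. draw under a Uniform(lower, upper) prior via a
    discretized conditional on a log grid."""
    n = resid.size
    ss = np.sum(resid ** 2)
    grid = np.exp(np.linspace(np.log(max(lower, 1e-4)), np.log(upper), n_grid))
    logp = -n * np.log(grid) - ss / (2 * grid ** 2) + np.log(grid)
    logp -= logp.max()
    p = np.exp(logp)
    return float(rng.choice(grid, p=p / p.sum()))
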