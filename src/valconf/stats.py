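"""Hierarchical regressions and signature curves for choice and confidence.

The descriptive layer of the analysis: a hierarchical logistic regression
of choice consistency and a hierarchical linear regression of confidence
reports on the trial regressors VD (absolute mean-rating difference),
Var (summed across-phase rating variance) and TV (summed mean rating),
with varying subject intercepts and slopes.  Regressors are z-scored
(pooled across subjects by default) so the reported coefficients are
standardized estimates.  "P-values" are posterior tail masses - the
portion of the population-level density on the far side of zero - never
frequentist p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import MCMCConfig, diagnostics

__all__ = ["RegressionResult", "HierarchicalRegression",
           "regress_consistency", "regress_confidence",
           "effect_size_contrast", "signature_curves", "population_frame"]


@dataclass
class RegressionResult:
    coef_names: list
    draws: dict                 # name -> population-slope draws
    sigma_draws: dict           # name -> population-spread draws
    subject_draws: np.ndarray   # (n_draws, S, P)
    diagnostics: object
    family: str
    standardized: bool

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for n in self.coef_names:
            d = self.draws[n]
            tail = float(min((d > 0).mean(), (d < 0).mean()))
            rows.append({"coef": n, "median": float(np.median(d)),
                         "sd": float(np.std(d)),
                         "ci_lo": float(np.quantile(d, 0.025)),
                         "ci_hi": float(np.quantile(d, 0.975)),
                         "tail_prob": tail})
        return pd.DataFrame(rows).set_index("coef")

    def covers_zero(self, name, level=0.95) -> bool:
        a = (1 - level) / 2
        lo, hi = np.quantile(self.draws[name], [a, 1 - a])
        return bool(lo <= 0 <= hi)

    def summary(self) -> str:
        t = self.coef_table()
        lines = ["Hierarchical %s regression (standardized=%s)"
                 % (self.family, self.standardized), t.to_string()]
        return "\n".join(lines)


class HierarchicalRegression:
    """Varying-intercept, varying-slope Bayesian regression.

    y_ns ~ family(b_s . x_ns); subject coefficient vectors b_s are drawn
    from independent population normals N(beta_p, sigma_p) per predictor,
    with flat priors on the population means and Uniform(0, 5) on the
    spreads.  family: "logistic" (Bernoulli) or "linear" (Gaussian with a
    shared residual s.d.).
    """

    def __init__(self, X, y, subject_idx, coef_names=None, family="logistic",
                 standardize=True, add_intercept=True):
        X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.subj = np.asarray(subject_idx, dtype=int)
        self.S = int(self.subj.max()) + 1
        if self.S == 1:
            warnings.warn("single subject: hierarchical spreads are "
                          "prior-dominated; effectively a flat regression")
        if standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        names = list(coef_names or [f"x{i}" for i in range(X.shape[1])])
        if add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["intercept"] + names
        self.X = X
        self.coef_names = names
        self.P = X.shape[1]
        self.family = family
        self.standardized = standardize

    def _pointwise_ll(self, coefs, sigma_e):
        """coefs (S, P) -> per-trial log-likelihood."""
        eta = np.einsum("np,np->n", self.X, coefs[self.subj])
        if self.family == "logistic":
            # log Bernoulli(sigmoid(eta))
            return self.y * eta - np.logaddexp(0.0, eta)
        return (-0.5 * np.log(2 * np.pi * sigma_e ** 2)
                - 0.5 * (self.y - eta) ** 2 / sigma_e ** 2)

    def _subject_ll(self, coefs, sigma_e):
        ll = self._pointwise_ll(coefs, sigma_e)
        out = np.zeros(self.S)
        np.add.at(out, self.subj, ll)
        return out

    def fit(self, config: MCMCConfig | None = None) -> RegressionResult:
        config = config or MCMCConfig(n_warmup=800, n_keep=500)
        S, P = self.S, self.P
        chain_store, subj_store = [], []
        for chain in range(config.n_chains):
            rng = np.random.default_rng(config.seed * 5077 + 31 * chain)
            coefs = np.zeros((S, P))
            if self.family == "linear":
                coefs[:, 0] = self.y.mean()
            beta = coefs.mean(axis=0)
            sig_pop = np.full(P, 0.3)
            sigma_e = max(self.y.std(), 0.1)
            step = np.full(P, 0.1)
            ll_s = self._subject_ll(coefs, sigma_e)
            keep, skeep = [], []
            total = config.n_warmup + config.n_keep * config.thinning
            for it in range(total):
                acc_rates = np.empty(P)
                for d in range(P):
                    prop = coefs.copy()
                    prop[:, d] += step[d] * rng.standard_normal(S)
                    lp = self._subject_ll(prop, sigma_e)
                    pr_old = -0.5 * ((coefs[:, d] - beta[d]) / sig_pop[d]) ** 2
                    pr_new = -0.5 * ((prop[:, d] - beta[d]) / sig_pop[d]) ** 2
                    acc = np.log(rng.uniform(size=S)) < lp - ll_s + pr_new - pr_old
                    coefs[acc, d] = prop[acc, d]
                    ll_s = np.where(acc, lp, ll_s)
                    acc_rates[d] = acc.mean()
                for d in range(P):
                    beta[d] = rng.normal(coefs[:, d].mean(),
                                         sig_pop[d] / np.sqrt(S))
                    sig_pop[d] = _grid_sigma(coefs[:, d] - beta[d], rng)
                if self.family == "linear":
                    resid = self.y - np.einsum("np,np->n", self.X,
                                               coefs[self.subj])
                    sigma_e = _grid_sigma(resid, rng, upper=5.0, n_grid=150)
                if it < config.n_warmup:
                    eta = min(1.0, 10.0 / (it + 20))
                    step *= np.exp(eta * (acc_rates - 0.35))
                elif (it - config.n_warmup + 1) % config.thinning == 0:
                    keep.append(beta.copy())
                    skeep.append(coefs.copy())
            chain_store.append(np.asarray(keep))
            subj_store.append(np.asarray(skeep))
        chains = np.stack(chain_store)
        diag = diagnostics(chains, names=self.coef_names)
        flat = chains.reshape(-1, P)
        draws = {n: flat[:, i] for i, n in enumerate(self.coef_names)}
        subject_draws = np.concatenate(subj_store, axis=0)
        sigma_draws = {n: subject_draws[:, :, i].std(axis=1)
                       for i, n in enumerate(self.coef_names)}
        return RegressionResult(coef_names=self.coef_names, draws=draws,
                                sigma_draws=sigma_draws,
                                subject_draws=subject_draws,
                                diagnostics=diag, family=self.family,
                                standardized=self.standardized)


def _grid_sigma(resid, rng, lower=1e-3, upper=5.0, n_grid=120):
    n = resid.size
    ss = np.sum(resid ** 2)
    grid = np.exp(np.linspace(np.log(lower), np.log(upper), n_grid))
    logp = -n * np.log(grid) - ss / (2 * grid ** 2) + np.log(grid)
    logp -= logp.max()
    p = np.exp(logp)
    return float(rng.choice(grid, p=p / p.sum()))


def population_frame(datasets) -> pd.DataFrame:
    """Stack per-subject trial frames with a subject index column."""
    frames = []
    for s, ds in enumerate(datasets):
        f = ds.to_frame()
        f["subject"] = s
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _design(df, require_var=True):
    cols = ["VD", "Var", "TV"]
    if df["Var"].isna().all():
        if require_var:
            raise ValueError("Var regressor unavailable (single-phase data)")
        cols = ["VD", "TV"]
    d = df.dropna(subset=[c for c in cols])
    return d, d[cols].to_numpy(), cols


def regress_consistency(df: pd.DataFrame, config: MCMCConfig | None = None,
                        standardize=True) -> RegressionResult:
    """Hierarchical logistic regression of consistency on VD, Var, TV.

    df : population trial frame (from :func:`population_frame`); tie trials
    are dropped (consistency undefined).
    """
    d = df[df["consistency"] != "tie"]
    d, X, cols = _design(d)
    y = (d["consistency"] == "consistent").astype(float).to_numpy()
    model = HierarchicalRegression(X, y, d["subject"].to_numpy(), cols,
                                   family="logistic",
                                   standardize=standardize)
    return model.fit(config)


def regress_confidence(df: pd.DataFrame, config: MCMCConfig | None = None,
                       standardize=True, extra_cols=()) -> RegressionResult:
    """Hierarchical linear regression of confidence on VD, Var, TV."""
    d, X, cols = _design(df)
    for c in extra_cols:
        X = np.column_stack([X, d[c].to_numpy()])
        cols = cols + [c]
    y = d["confidence"].to_numpy()
    model = HierarchicalRegression(X, y, d["subject"].to_numpy(), cols,
                                   family="linear", standardize=standardize)
    return model.fit(config)


def effect_size_contrast(res_a: RegressionResult, res_b: RegressionResult,
                         coef: str, rng=None):
    """Draw-wise difference of standardized effect sizes for one regressor.

    Effect size per draw is the population slope over the population
    spread of that slope; returns (delta draws, summary dict with the
    posterior tail mass of the difference).
    """
    if coef not in res_a.draws or coef not in res_b.draws:
        raise ValueError(f"coefficient {coef!r} missing from one result")
    rng = np.random.default_rng(rng)
    ea = res_a.draws[coef] / np.maximum(res_a.sigma_draws[coef], 1e-6)
    eb = res_b.draws[coef] / np.maximum(res_b.sigma_draws[coef], 1e-6)
    m = min(ea.size, eb.size)
    if ea.size != eb.size:
        ea = rng.choice(ea, m, replace=False)
        eb = rng.choice(eb, m, replace=False)
    delta = ea - eb
    tail = float(min((delta > 0).mean(), (delta < 0).mean()))
    return delta, {"median": float(np.median(delta)),
                   "sd": float(np.std(delta)), "tail_prob": tail}


def _equal_count_bins(x, n_bins):
    order = np.argsort(x, kind="stable")
    idx = np.empty(len(x), dtype=int)
    # contiguous equal-count assignment: bin sizes differ by at most 1
    splits = np.array_split(order, n_bins)
    for b, s in enumerate(splits):
        idx[s] = b
    return idx


def _curve(x, y, n_bins, min_per_cell=3):
    idx = _equal_count_bins(x, n_bins)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < min_per_cell:
            continue
        rows.append({"bin": b, "x": float(np.mean(x[sel])),
                     "y": float(np.mean(y[sel])),
                     "sem": float(np.std(y[sel]) / np.sqrt(max(n, 1))),
                     "n": n})
    return pd.DataFrame(rows)


def signature_curves(df: pd.DataFrame, n_bins=8) -> dict:
    """Canonical binned confidence/choice signatures.

    Equal-count bins (sizes differ by <= 1): confidence vs |VD| split by
    consistency, confidence vs RT, confidence vs TV, choice proportion vs
    VD, and P(choose upper) vs dwell-share difference median-split by
    confidence.
    """
    out = {}
    d = df[df["consistency"] != "tie"]
    for lab in ("consistent", "inconsistent"):
        sub = d[d["consistency"] == lab]
        k = min(n_bins, max(len(sub) // 8, 1))
        if len(sub) >= 3:
            out[f"confidence_vs_vd_{lab}"] = _curve(
                sub["VD"].to_numpy(), sub["confidence"].to_numpy(), k)
    out["confidence_vs_rt"] = _curve(df["rt_s"].to_numpy(),
                                     df["confidence"].to_numpy(), n_bins)
    out["confidence_vs_tv"] = _curve(df["TV"].to_numpy(),
                                     df["confidence"].to_numpy(), n_bins)
    out["consistency_vs_vd"] = _curve(
        d["VD"].to_numpy(),
        (d["consistency"] == "consistent").to_numpy(float), n_bins)
    dd = 2 * df["g_upper"].to_numpy() - 1
    hi = df["confidence"].to_numpy() >= np.median(df["confidence"])
    for lab, mask in (("high_conf", hi), ("low_conf", ~hi)):
        out[f"choice_vs_dwell_{lab}"] = _curve(
            dd[mask], df["choice_upper"].to_numpy(float)[mask], n_bins)
    return out
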