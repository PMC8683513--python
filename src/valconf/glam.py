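"""Gaze-weighted linear accumulator (GLAM) race model.

Two independent accumulators race toward a common bound B.  The drift of
each accumulator is ``k * R_i`` where ``R_i`` is a logistic transform of the
difference between gaze-weighted value signals:

    S_i = g_i v_i + (1 - g_i) * theta * v_i
    R_i = 1 / (1 + exp(-tau * (S_i - S_j)))

``theta <= 1`` is the attentional effort applied to the momentarily
non-fixated option (theta = 1: no discounting; theta = 0: the unattended
option is ignored).  First-passage times of a single accumulator follow a
Wald (inverse Gaussian) distribution with mean ``mu = B / (k R)`` and shape
``lam = B^2 / sigma^2``; the race likelihood of observing the winner at time
t is ``f_winner(t) * (1 - F_loser(t))``.

The bound is fixed at B = 1 for identifiability (only B/k and B/sigma are
identified).  There is no non-decision-time parameter; an optional fixed
offset hook exists in :class:`GLAMModel` for extension work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "GLAMParams",
    "RaceOutcome",
    "drift_terms",
    "wald_pdf",
    "wald_logpdf",
    "wald_cdf",
    "wald_logsf",
    "race_density",
    "race_loglik",
    "simulate_trial",
    "simulate_trials",
    "GLAMModel",
    "GLAMResults",
]

_TINY = 1e-300


@dataclass(frozen=True)
class GLAMParams:
    """Parameters of the gaze-weighted race.

    k : evidence gain (drift scale, 1/s), > 0
    sigma : accumulation noise s.d. (1/sqrt(s)), > 0
    tau : logistic scaling of the evidence difference, > 0
    theta : attentional effort in (-inf, 1]
    B : decision bound, fixed (default 1)
    """

    k: float
    sigma: float
    tau: float
    theta: float
    B: float = 1.0

    def __post_init__(self):
        if self.k <= 0 or self.sigma <= 0 or self.tau <= 0 or self.B <= 0:
            raise ValueError("k, sigma, tau and B must all be positive")

    def replace(self, **kw) -> "GLAMParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class RaceOutcome:
    winner: str            # "upper" or "lower"
    rt_s: float
    loser_evidence: float  # location of the losing accumulator, < B
    timeout: bool = False


def drift_terms(v_i, v_j, g_i, params: GLAMParams, theta=None, k=None):
    """Relative evidence signals (R_i, R_j) for a trial.

    ``theta`` / ``k`` override the values in ``params`` (used for
    trial-varying latents).  All arguments broadcast.
    """
    th = params.theta if theta is None else theta
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    g_i = np.asarray(g_i, dtype=float)
    g_j = 1.0 - g_i
    s_i = g_i * v_i + (1.0 - g_i) * th * v_i
    s_j = g_j * v_j + (1.0 - g_j) * th * v_j
    x = params.tau * (s_i - s_j)
    r_i = expit(x)
    return r_i, 1.0 - r_i


def _mu_lam(B, k, R, sigma):
    with np.errstate(divide="ignore", over="ignore"):
        mu = B / (k * np.asarray(R, dtype=float))
    lam = B * B / (sigma * sigma)
    return mu, lam


def wald_logpdf(t, B, k, R, sigma):
    t = np.asarray(t, dtype=float)
    mu, lam = _mu_lam(B, k, R, sigma)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        out = 0.5 * (np.log(lam) - np.log(2 * np.pi) - 3 * np.log(t)) \
            - lam * (t - mu) ** 2 / (2 * mu ** 2 * t)
    return np.where(t > 0, out, -np.inf)


def wald_pdf(t, B, k, R, sigma):
    """First-passage density of a single accumulator (Wald / inverse Gaussian).

    mu = B/(kR), lam = B^2/sigma^2; density 0 for t <= 0.
    """
    return np.exp(wald_logpdf(t, B, k, R, sigma))


def wald_cdf(t, B, k, R, sigma):
    """First-passage CDF, evaluated stably in log space.

    F(t) = Phi(sqrt(lam/t)(t/mu - 1)) + exp(2 lam / mu) Phi(-sqrt(lam/t)(t/mu + 1))

    The second term overflows naively for large lam/mu; it is computed as
    exp(2 lam/mu + log Phi(.)) which is finite whenever F is.
    """
    t = np.asarray(t, dtype=float)
    mu, lam = _mu_lam(B, k, R, sigma)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        srt = np.sqrt(lam / t)
        a = srt * (t / mu - 1.0)
        b = -srt * (t / mu + 1.0)
        second = np.exp(2.0 * lam / mu + log_ndtr(b))
        out = ndtr(a) + second
    out = np.where(t > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def wald_logsf(t, B, k, R, sigma):
    """log(1 - F(t)), guarded against catastrophic cancellation near F = 1."""
    t = np.asarray(t, dtype=float)
    mu, lam = _mu_lam(B, k, R, sigma)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        srt = np.sqrt(lam / t)
        a = srt * (t / mu - 1.0)
        b = -srt * (t / mu + 1.0)
        log_first = log_ndtr(-a)                    # Phi(-a)
        log_second = 2.0 * lam / mu + log_ndtr(b)   # exp(2lam/mu) Phi(b)
        # 1 - F = Phi(-a) - exp(2lam/mu) Phi(b) >= 0
        diff = -np.expm1(np.minimum(log_second - log_first, 0.0))
        out = log_first + np.log(np.maximum(diff, _TINY))
    return np.where(t > 0, out, 0.0)


def race_density(t, winner, v_up, v_low, g_up, params: GLAMParams,
                 theta=None, k=None):
    """Defective density of (winner, t): f_winner(t) * (1 - F_loser(t))."""
    return np.exp(race_logdensity(t, winner, v_up, v_low, g_up, params,
                                  theta=theta, k=k))


def race_logdensity(t, winner, v_up, v_low, g_up, params: GLAMParams,
                    theta=None, k=None):
    r_up, r_low = drift_terms(v_up, v_low, g_up, params, theta=theta, k=k)
    kk = params.k if k is None else np.asarray(k, dtype=float)
    up_wins = np.asarray(winner)
    if up_wins.dtype.kind in "US":
        up_wins = up_wins == "upper"
    up_wins = up_wins.astype(bool)
    r_win = np.where(up_wins, r_up, r_low)
    r_lose = np.where(up_wins, r_low, r_up)
    return (wald_logpdf(t, params.B, kk, r_win, params.sigma)
            + wald_logsf(t, params.B, kk, r_lose, params.sigma))


def race_loglik(rts, choices_upper, v_up, v_low, g_up, params: GLAMParams,
                theta=None, k=None):
    """Summed race log-likelihood over trials; per-trial terms on request.

    choices_upper : boolean array, True where the upper item won.
    """
    ll = race_logdensity(np.asarray(rts, float), np.asarray(choices_upper, bool),
                         v_up, v_low, g_up, params, theta=theta, k=k)
    return ll


def simulate_trials(v_up, v_low, g_up, params: GLAMParams, dt=0.001,
                    deadline=4.0, rng=None, theta=None, k=None):
    """Euler-Maruyama simulation of the race for many trials at once.

    e(t + dt) = e(t) + k R dt + N(0, sigma^2 dt).  The bound crossing is
    located by linear interpolation inside the crossing step, and the loser
    accumulator is read out (interpolated) at that instant.

    Returns dict of arrays: choice_upper (bool), rt_s, loser_evidence,
    timeout (bool).
    """
    rng = np.random.default_rng(rng)
    r_up, r_low = drift_terms(v_up, v_low, g_up, params, theta=theta)
    kk = params.k if k is None else np.asarray(k, dtype=float)
    n = np.broadcast(np.asarray(v_up, float), np.asarray(g_up, float),
                     np.asarray(r_up)).size
    r_up = np.broadcast_to(r_up, (n,)).astype(float)
    r_low = np.broadcast_to(r_low, (n,)).astype(float)
    d_up = np.broadcast_to(kk * r_up, (n,)).astype(float) * dt
    d_low = np.broadcast_to(kk * r_low, (n,)).astype(float) * dt
    sd = params.sigma * np.sqrt(dt)
    B = params.B

    e_up = np.zeros(n)
    e_low = np.zeros(n)
    active = np.arange(n)
    choice_upper = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    loser = np.full(n, np.nan)
    timeout = np.zeros(n, dtype=bool)

    max_steps = int(np.ceil(deadline / dt))
    for step in range(1, max_steps + 1):
        m = active.size
        if m == 0:
            break
        new_up = e_up[active] + d_up[active] + sd * rng.standard_normal(m)
        new_low = e_low[active] + d_low[active] + sd * rng.standard_normal(m)
        crossed = (new_up >= B) | (new_low >= B)
        if crossed.any():
            idx = active[crossed]
            nu, nl = new_up[crossed], new_low[crossed]
            ou, ol = e_up[idx], e_low[idx]
            # interpolated crossing fraction within the step for each side
            with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
                a_up = np.where(nu >= B, (B - ou) / (nu - ou), np.inf)
                a_low = np.where(nl >= B, (B - ol) / (nl - ol), np.inf)
            up_first = a_up <= a_low
            frac = np.where(up_first, a_up, a_low)
            choice_upper[idx] = up_first
            rt[idx] = (step - 1 + frac) * dt
            lo_old = np.where(up_first, ol, ou)
            lo_new = np.where(up_first, nl, nu)
            le = lo_old + frac * (lo_new - lo_old)
            loser[idx] = np.minimum(le, np.nextafter(B, -np.inf))
        e_up[active] = new_up
        e_low[active] = new_low
        active = active[~crossed]

    if active.size:
        timeout[active] = True
        rt[active] = deadline
        win_up = e_up[active] >= e_low[active]
        choice_upper[active] = win_up
        loser[active] = np.where(win_up, e_low[active], e_up[active])
    return {"choice_upper": choice_upper, "rt_s": rt,
            "loser_evidence": loser, "timeout": timeout}


def simulate_trial(v_up, v_low, g_up, params: GLAMParams, dt=0.001,
                   deadline=4.0, seed=None, theta=None, k=None) -> RaceOutcome:
    """Simulate a single race trial; see :func:`simulate_trials`."""
    out = simulate_trials([v_up], [v_low], [g_up], params, dt=dt,
                          deadline=deadline, rng=seed, theta=theta, k=k)
    return RaceOutcome(
        winner="upper" if out["choice_upper"][0] else "lower",
        rt_s=float(out["rt_s"][0]),
        loser_evidence=float(out["loser_evidence"][0]),
        timeout=bool(out["timeout"][0]),
    )


# ---------------------------------------------------------------------------
# Fitting


def _unpack(x):
    # x = (log k, log sigma, log tau, u) with theta = 1 - exp(u) <= 1
    k, sigma, tau = np.exp(x[:3])
    theta = 1.0 - np.exp(x[3])
    return k, sigma, tau, theta


def _pack(k, sigma, tau, theta):
    return np.array([np.log(k), np.log(sigma), np.log(tau),
                     np.log(max(1.0 - theta, 1e-6))])


@dataclass
class GLAMResults:
    """MAP (or posterior-summary) fit of the race model for one subject."""

    params: GLAMParams
    se: dict
    loglik: float
    n_trials: int
    converged: bool
    draws: dict | None = None
    diagnostics: dict | None = None

    def summary(self) -> str:
        lines = ["GLAM fit (B = %.3g fixed)" % self.params.B,
                 "n_trials = %d   loglik = %.2f   converged = %s"
                 % (self.n_trials, self.loglik, self.converged),
                 "%-8s %10s %10s" % ("param", "estimate", "se")]
        for name in ("k", "sigma", "tau", "theta"):
            lines.append("%-8s %10.4f %10.4f"
                         % (name, getattr(self.params, name),
                            self.se.get(name, float("nan"))))
        return "\n".join(lines)


class GLAMModel:
    """Race model for one subject's (choice, RT) data given values and gaze.

    Parameters
    ----------
    rts, choices_upper, v_up, v_low, g_up : array-like, one entry per trial.
    ndt : fixed non-decision offset in seconds subtracted from RTs
        (default 0; extension hook only).
    """

    def __init__(self, rts, choices_upper, v_up, v_low, g_up, ndt=0.0):
        self.rts = np.asarray(rts, dtype=float) - ndt
        self.choices_upper = np.asarray(choices_upper, dtype=bool)
        self.v_up = np.asarray(v_up, dtype=float)
        self.v_low = np.asarray(v_low, dtype=float)
        self.g_up = np.asarray(g_up, dtype=float)
        if not np.all(self.rts > 0):
            raise ValueError("all reaction times must be positive")
        if np.ptp(self.rts) == 0:
            raise ValueError("degenerate data: all reaction times identical")
        self.n_trials = self.rts.size
        if self.n_trials < 50:
            import warnings
            warnings.warn("fewer than 50 trials; race-model fit may be unstable")

    @classmethod
    def from_dataset(cls, ds, **kw):
        """Build from a :class:`~valconf.data.SubjectDataset` (valid trials)."""
        tr = ds.valid_trials()
        return cls(
            rts=[t.rt_s for t in tr],
            choices_upper=[t.choice == "upper" for t in tr],
            v_up=[t.v_upper for t in tr],
            v_low=[t.v_lower for t in tr],
            g_up=[t.g_upper for t in tr],
            **kw,
        )

    def loglik(self, params: GLAMParams, theta=None, k=None):
        return float(np.sum(race_loglik(
            self.rts, self.choices_upper, self.v_up, self.v_low, self.g_up,
            params, theta=theta, k=k)))

    def _neg_logpost(self, x):
        k, sigma, tau, theta = _unpack(x)
        if not np.isfinite(k * sigma * tau) or k > 1e4 or sigma > 1e3:
            return 1e12
        p = GLAMParams(k=k, sigma=sigma, tau=tau, theta=theta)
        ll = self.loglik(p)
        # weak log-normal regularization keeps the optimizer on-scale
        prior = -0.5 * np.sum((x[:3] / 5.0) ** 2) - 0.5 * (x[3] / 5.0) ** 2
        if not np.isfinite(ll):
            return 1e12
        return -(ll + prior)

    def fit(self, start: GLAMParams | None = None, n_restarts: int = 3,
            seed: int = 0) -> GLAMResults:
        """MAP estimate with Hessian-based standard errors.

        Multiple optimizer restarts guard against local optima of the
        race likelihood; the best solution is kept.
        """
        rng = np.random.default_rng(seed)
        starts = []
        if start is not None:
            starts.append(_pack(start.k, start.sigma, start.tau, start.theta))
        base = _pack(1.0 / max(np.median(self.rts), 1e-2) * 2.0, 1.0, 5.0, 0.5)
        starts.append(base)
        for _ in range(max(0, n_restarts - len(starts))):
            starts.append(base + rng.normal(scale=0.5, size=4))
        best = None
        for x0 in starts:
            res = optimize.minimize(self._neg_logpost, x0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-6,
                                             "fatol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
        k, sigma, tau, theta = _unpack(best.x)
        params = GLAMParams(k=k, sigma=sigma, tau=tau, theta=theta)
        se = self._hessian_se(best.x)
        return GLAMResults(params=params, se=se, loglik=self.loglik(params),
                           n_trials=self.n_trials, converged=bool(best.success))

    def _hessian_se(self, x):
        # numerical Hessian of the negative log posterior, delta-method
        # mapped through the parameter transforms
        eps = 1e-4
        n = x.size
        H = np.zeros((n, n))
        f = self._neg_logpost
        for i in range(n):
            for j in range(i, n):
                ei = np.eye(n)[i] * eps
                ej = np.eye(n)[j] * eps
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps * eps)
        try:
            cov = np.linalg.inv(H)
            var = np.clip(np.diag(cov), 0, np.inf)
        except np.linalg.LinAlgError:
            var = np.full(n, np.nan)
        k, sigma, tau, theta = _unpack(x)
        # d(param)/d(x): exp transforms
        jac = np.array([k, sigma, tau, -(1.0 - theta)])
        se = np.sqrt(var) * np.abs(jac)
        return dict(zip(("k", "sigma", "tau", "theta"), se))
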