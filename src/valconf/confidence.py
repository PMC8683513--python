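"""Generative models of decision confidence for the gaze-weighted race.

Two readouts are implemented:

* **Heuristic (balance of evidence).** Confidence is the distance of the
  losing accumulator from the decision bound at choice time,
  ``confidence = B - e_loser(t)``.  Because the experimenter observes the
  RT but not the loser's location, the trial-level prediction marginalizes
  the loser location: the expected confidence at time t is
  ``B - ((k R) t + phi(beta)/Phi(beta) * sigma * sqrt(t))`` with
  ``beta = (B - (k R) t) / (sigma sqrt(t))``.  Note that the textbook mean
  of a normal truncated *below* the bound carries the Mills-ratio term with
  the opposite sign; both variants are available through
  ``loser_mean_variant`` ("as_printed", the default, and "truncated") and
  the discrepancy is adjudicated against a Monte-Carlo oracle in the test
  suite.

* **Normative (probability correct).** Confidence is the probability that
  the choice was correct given the decision time, the choice class, the
  process parameters and the contextual statistics of the task.  The
  contextual association P(correct | t, e_loser) is estimated by
  simulating races across the session's trial configurations
  (:func:`build_context_table`); predictions then marginalize the
  unobserved loser evidence with its model-implied density (normal with
  mean (kR)t and variance sigma^2 t, truncated below B).

Only the normative readout inherits the accuracy benefit of higher
attentional effort theta, which is the key contrast between the two
model families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr

from .glam import GLAMParams, drift_terms, simulate_trials

__all__ = ["heuristic_confidence", "expected_heuristic_confidence",
           "ContextTable", "build_context_table", "normative_confidence",
           "NormativePredictor"]


def heuristic_confidence(loser_evidence, B=1.0):
    """Balance-of-evidence confidence B - e_loser (unnormalized).

    The loser accumulator must lie strictly below the bound.
    """
    e = np.asarray(loser_evidence, dtype=float)
    if np.any(e >= B):
        raise ValueError("loser evidence must lie strictly below the bound B")
    return B - e


def _log_mills(beta):
    """log of phi(beta)/Phi(beta), stable for very negative beta."""
    beta = np.asarray(beta, dtype=float)
    logphi = -0.5 * (np.log(2 * np.pi) + beta ** 2)
    return logphi - log_ndtr(beta)


def expected_heuristic_confidence(rt, R_loser, params: GLAMParams, k=None,
                                  loser_mean_variant="as_printed"):
    """Expected balance-of-evidence confidence for a given RT.

    ``as_printed`` evaluates B - ((kR)t + Mills * sigma sqrt(t)); the
    ``truncated`` variant uses the mean of the loser's normal distribution
    truncated below B, B - ((kR)t - Mills * sigma sqrt(t)).  The Mills
    ratio is evaluated in log space to survive Phi underflow.
    """
    t = np.asarray(rt, dtype=float)
    if np.any(t <= 0):
        raise ValueError("rt must be positive")
    kk = params.k if k is None else np.asarray(k, dtype=float)
    m = kk * np.asarray(R_loser, dtype=float) * t
    s = params.sigma * np.sqrt(t)
    beta = (params.B - m) / s
    mills = np.exp(_log_mills(beta))
    if loser_mean_variant == "as_printed":
        return params.B - (m + mills * s)
    elif loser_mean_variant == "truncated":
        return params.B - (m - mills * s)
    raise ValueError("loser_mean_variant must be 'as_printed' or 'truncated'")


@dataclass
class ContextTable:
    """Simulation-based estimate of P(correct | rt bin, loser-evidence bin).

    Built by racing the model across a set of trial contexts (value pairs
    and gaze shares with uniform weight) and recording, for each (rt,
    loser-evidence) cell, the smoothed fraction of races in which the
    winner was the higher-value item.
    """

    rt_edges: np.ndarray          # (n_rt + 1,)
    e_edges: np.ndarray           # (n_e + 1,)
    table: np.ndarray             # (n_rt, n_e) probabilities in [0, 1]
    counts: np.ndarray            # (n_rt, n_e) simulated races per cell
    marginal_accuracy: float
    params: GLAMParams = None
    n_sim: int = 0
    seed: int | None = None

    def lookup(self, rt, e):
        """Nearest-bin table lookup (clamped at the support edges)."""
        i = np.clip(np.searchsorted(self.rt_edges, rt, side="right") - 1,
                    0, self.table.shape[0] - 1)
        j = np.clip(np.searchsorted(self.e_edges, e, side="right") - 1,
                    0, self.table.shape[1] - 1)
        return self.table[i, j]


def build_context_table(trial_contexts, params: GLAMParams, n_sim=100_000,
                        rt_bins=20, e_bins=25, seed=0, dt=0.001,
                        deadline=4.0) -> ContextTable:
    """Estimate the contextual association P(correct | t, e_loser).

    trial_contexts : array-like (n_ctx, 3) of (v_upper, v_lower, g_upper)
        rows; these define the uniform empirical context distribution.
    The table uses RT quantile bins of the simulated RT distribution and
    linear loser-evidence bins; cells are add-one smoothed toward the
    marginal simulated accuracy, which also fills unreachable cells.
    """
    ctx = np.atleast_2d(np.asarray(trial_contexts, dtype=float))
    if ctx.shape[0] == 0:
        raise ValueError("trial_contexts must be nonempty")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, ctx.shape[0], size=int(n_sim))
    v_up, v_low, g_up = ctx[pick, 0], ctx[pick, 1], ctx[pick, 2]
    out = simulate_trials(v_up, v_low, g_up, params, dt=dt,
                          deadline=deadline, rng=rng)
    ok = ~out["timeout"] & (v_up != v_low)
    rt = out["rt_s"][ok]
    e = out["loser_evidence"][ok]
    correct = np.where(out["choice_upper"][ok], v_up[ok] > v_low[ok],
                       v_low[ok] > v_up[ok])
    marg = float(correct.mean()) if correct.size else 0.5

    qs = np.linspace(0, 1, rt_bins + 1)
    rt_edges = np.quantile(rt, qs)
    rt_edges[0], rt_edges[-1] = 0.0, max(rt_edges[-1], deadline)
    rt_edges = np.unique(rt_edges)
    lo = min(np.min(e), params.B - 6 * params.sigma * np.sqrt(np.median(rt)))
    e_edges = np.linspace(lo, params.B, e_bins + 1)

    i = np.clip(np.searchsorted(rt_edges, rt, side="right") - 1, 0,
                len(rt_edges) - 2)
    j = np.clip(np.searchsorted(e_edges, e, side="right") - 1, 0, e_bins - 1)
    shape = (len(rt_edges) - 1, e_bins)
    counts = np.zeros(shape)
    hits = np.zeros(shape)
    np.add.at(counts, (i, j), 1)
    np.add.at(hits, (i, j), correct.astype(float))
    table = (hits + marg) / (counts + 1.0)   # one pseudo-count at the marginal
    return ContextTable(rt_edges=rt_edges, e_edges=e_edges, table=table,
                        counts=counts, marginal_accuracy=marg, params=params,
                        n_sim=int(n_sim), seed=seed)


def _loser_density_grid(table: ContextTable, rt, r_loser, k=None):
    """Loser-evidence density on the table's e-grid at time rt.

    Normal with mean (k R_loser) t and variance sigma^2 t, truncated below
    the bound and renormalized on the grid.  Vectorized over trials.
    Returns (centers, weights) with weights summing to 1 per trial.
    """
    p = table.params
    kk = p.k if k is None else np.asarray(k, dtype=float)
    t = np.atleast_1d(np.asarray(rt, dtype=float))
    m = np.atleast_1d(kk * np.asarray(r_loser, dtype=float) * t)
    s = p.sigma * np.sqrt(t)
    centers = 0.5 * (table.e_edges[:-1] + table.e_edges[1:])
    z = (centers[None, :] - m[:, None]) / s[:, None]
    logw = -0.5 * z * z
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return centers, w


def normative_confidence(choice_class, rt, v_up, v_low, g_up,
                         table: ContextTable, theta=None, k=None,
                         warn_extrapolate=True):
    """Probability-correct confidence prediction for observed trials.

    choice_class : "correct" / "incorrect" per trial (consistency of the
        observed choice with the higher-value item); selects which
        accumulator is the loser when forming the loser-evidence density.
    The prediction is sum_e P(correct | t, e) p(e | C, t) over the table's
    evidence grid.  RTs outside the table support use the nearest bin.
    """
    p = table.params
    t = np.atleast_1d(np.asarray(rt, dtype=float))
    cls = np.atleast_1d(np.asarray(choice_class))
    if cls.dtype.kind in "US":
        correct_class = cls == "correct"
    else:
        correct_class = cls.astype(bool)
    r_up, r_low = drift_terms(v_up, v_low, g_up, p, theta=theta)
    r_up = np.broadcast_to(r_up, t.shape)
    r_low = np.broadcast_to(r_low, t.shape)
    hv_up = np.broadcast_to(np.asarray(v_up, float) >= np.asarray(v_low, float),
                            t.shape)
    # loser: the lower-value item on correct-class trials, else the higher
    r_hv = np.where(hv_up, r_up, r_low)
    r_lv = np.where(hv_up, r_low, r_up)
    r_loser = np.where(correct_class, r_lv, r_hv)
    if warn_extrapolate and (np.any(t < table.rt_edges[0]) or
                             np.any(t > table.rt_edges[-1])):
        import warnings
        warnings.warn("rt outside context-table support; nearest bin used")
    centers, w = _loser_density_grid(table, t, r_loser, k=k)
    i = np.clip(np.searchsorted(table.rt_edges, t, side="right") - 1, 0,
                table.table.shape[0] - 1)
    pc = np.sum(table.table[i, :] * w, axis=1)
    return pc if np.ndim(rt) else float(pc[0])


class NormativePredictor:
    """Normative confidence with trial-varying (theta, k) latents.

    The context table depends on the process parameters, so trial-varying
    latents require a family of tables.  Tables are built lazily on a
    small grid spanning the latent range and each trial uses the table at
    the nearest grid node (with the trial's own drift terms in the
    loser-evidence density).
    """

    def __init__(self, trial_contexts, params: GLAMParams, n_sim=20_000,
                 n_grid=5, rt_bins=15, e_bins=25, seed=0, dt=0.002):
        self.contexts = np.atleast_2d(np.asarray(trial_contexts, float))
        self.params = params
        self.n_sim = int(n_sim)
        self.n_grid = int(n_grid)
        self.rt_bins = rt_bins
        self.e_bins = e_bins
        self.seed = seed
        self.dt = dt
        self._tables: dict[tuple, ContextTable] = {}

    def _table_for(self, theta, k):
        key = (round(float(theta), 6), round(float(k), 6))
        if key not in self._tables:
            p = self.params.replace(theta=float(theta), k=float(k))
            self._tables[key] = build_context_table(
                self.contexts, p, n_sim=self.n_sim, rt_bins=self.rt_bins,
                e_bins=self.e_bins, seed=self.seed + len(self._tables),
                dt=self.dt)
        return self._tables[key]

    def predict(self, choice_class, rt, v_up, v_low, g_up, theta=None, k=None):
        """Per-trial normative predictions; theta/k may be per-trial arrays."""
        t = np.atleast_1d(np.asarray(rt, float))
        n = t.size
        th = np.broadcast_to(
            np.asarray(self.params.theta if theta is None else theta, float), (n,))
        kk = np.broadcast_to(
            np.asarray(self.params.k if k is None else k, float), (n,))
        th_nodes = np.unique(np.round(np.linspace(th.min(), th.max(),
                                                  self.n_grid), 6))
        k_nodes = np.unique(np.round(np.linspace(kk.min(), kk.max(),
                                                 max(2, self.n_grid // 2)), 6))
        i_th = np.argmin(np.abs(th[:, None] - th_nodes[None, :]), axis=1)
        i_k = np.argmin(np.abs(kk[:, None] - k_nodes[None, :]), axis=1)
        out = np.empty(n)
        cls = np.atleast_1d(np.asarray(choice_class))
        v_up = np.broadcast_to(np.asarray(v_up, float), (n,))
        v_low = np.broadcast_to(np.asarray(v_low, float), (n,))
        g_up = np.broadcast_to(np.asarray(g_up, float), (n,))
        for a in range(len(th_nodes)):
            for b in range(len(k_nodes)):
                sel = (i_th == a) & (i_k == b)
                if not sel.any():
                    continue
                tab = self._table_for(th_nodes[a], k_nodes[b])
                out[sel] = normative_confidence(
                    cls[sel], t[sel], v_up[sel], v_low[sel], g_up[sel], tab,
                    theta=th[sel], k=kk[sel], warn_extrapolate=False)
        return out
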