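"""Quick-look figures for sessions, fits and signature curves.

All functions return a matplotlib Figure and never call show(); callers
decide how to render or save.
"""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_signature_curves(curves: dict, ncols=3):
    """Grid of the binned confidence/choice signatures from
    :func:`valconf.stats.signature_curves`."""
    plt = _pyplot()
    names = list(curves)
    nrows = int(np.ceil(len(names) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), names):
        c = curves[name]
        ax.errorbar(c["x"], c["y"], yerr=c["sem"], marker="o", lw=1.2,
                    capsize=2)
        ax.set_title(name.replace("_", " "), fontsize=9)
    for ax in axes.ravel()[len(names):]:
        ax.axis("off")
    fig.tight_layout()
    return fig


def plot_race_fit(results, rts, choices_upper, v_up, v_low, g_up, bins=30):
    """Observed RT histograms (per choice side) against the fitted race
    density from a :class:`~valconf.glam.GLAMResults`."""
    from .glam import race_density

    plt = _pyplot()
    rts = np.asarray(rts, float)
    choices_upper = np.asarray(choices_upper, bool)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    t = np.linspace(1e-3, max(rts.max() * 1.1, 1.0), 300)
    for ax, side, sel in ((axes[0], "upper", choices_upper),
                          (axes[1], "lower", ~choices_upper)):
        ax.hist(rts[sel], bins=bins, density=False, alpha=0.5,
                weights=np.full(sel.sum(), 1.0 / rts.size / (
                    (rts[sel].max() - rts[sel].min()) / bins or 1.0)),
                label="observed")
        dens = np.mean([race_density(t, side, vu, vl, g, results.params)
                        for vu, vl, g in zip(v_up, v_low, g_up)], axis=0)
        ax.plot(t, dens, lw=2, label="fitted race")
        ax.set_title(f"chose {side}")
        ax.set_xlabel("RT (s)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_joint_posterior(results, names=("rho_ctheta", "rho_ck",
                                         "rho_ktheta")):
    """Marginal posterior histograms of linking correlations from a
    :class:`~valconf.joint.JointResults`."""
    plt = _pyplot()
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3))
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        d = results.hyper_draws[name]
        ax.hist(d, bins=40, alpha=0.7)
        ax.axvline(np.median(d), color="k", lw=1)
        ax.set_title(name)
        ax.set_xlim(-1, 1)
    fig.tight_layout()
    return fig
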