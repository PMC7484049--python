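"""Minimal figure helpers mirroring the standard diagnostic plots.

Cosmetic fidelity is out of scope; these produce line/scatter summaries of
sweep tables, resonance profiles and annotated time series for quick visual
inspection.  Matplotlib is imported lazily so headless use stays cheap.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_bifurcation(df, param_label: str = "parameter"):
    """Three panels: attractor samples, Lyapunov exponent, merging condition."""
    plt = _plt()
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 8))
    for _, row in df.iterrows():
        ys = np.fromstring(row["x_samples"], sep=";")
        axes[0].plot(np.full_like(ys, row["param"]), ys, ".", ms=1, color="C0")
    axes[0].set_ylabel("x(n)")
    axes[1].plot(df["param"], df["lambda"], lw=0.8)
    axes[1].axhline(0, color="k", lw=0.5)
    axes[1].set_ylabel(r"$\lambda$")
    axes[2].plot(df["param"], df["g_fmax"], label=r"$g(f_{max})$")
    axes[2].plot(df["param"], df["g_fmin"], label=r"$g(f_{min})$")
    axes[2].axhline(0, color="k", lw=0.5)
    axes[2].set_ylabel("merging condition")
    axes[2].set_xlabel(param_label)
    axes[2].legend()
    fig.tight_layout()
    return fig


def plot_resonance(profile):
    """Ensemble maxτC(τ) and Ξ versus K with K_peak / K* markers."""
    plt = _plt()
    df = profile.to_frame()
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.errorbar(df["K"], df["mean_max_corr"], yerr=df["sd_max_corr"],
                 color="k", lw=1, elinewidth=0.6)
    ax1.axvline(profile.K_peak, color="C3", ls="--", label=f"K_peak={profile.K_peak:g}")
    if profile.K_star is not None:
        ax1.axvline(profile.K_star, color="C2", ls=":", label=f"K*={profile.K_star:.3f}")
    ax1.set_ylabel(r"$\max_\tau C(\tau)$")
    ax1.legend()
    ax2.errorbar(df["K"], df["mean_xi"], yerr=df["sd_xi"], color="k", lw=1,
                 elinewidth=0.6)
    ax2.set_ylabel(r"$\Xi$")
    ax2.set_xlabel("K")
    fig.suptitle(f"A={profile.A:g}, alpha={profile.alpha:g}, p={profile.p}")
    fig.tight_layout()
    return fig


def plot_timeseries(traj, n_show: int = 500):
    """Orbit with the periodic drive overlaid (drive scaled for visibility)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 3))
    n = traj.steps()[:n_show]
    ax.plot(n, traj.x[:n_show], lw=0.7, label="x(n)")
    if traj.drive.alpha > 0:
        scale = np.max(np.abs(traj.x[:n_show])) / traj.drive.alpha
        ax.plot(n, traj.s[:n_show] * scale, lw=0.7, alpha=0.7,
                label="S(n) (scaled)")
    ax.axhline(traj.control.x_d, color="k", lw=0.5)
    ax.set_xlabel("n (days)")
    ax.set_ylabel("x")
    ax.legend(loc="upper right")
    fig.tight_layout()
    return fig
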