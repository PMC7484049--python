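"""Synchronization and perturbation-budget metrics.

Synchronization of the orbit x(n) to the periodic drive S(n) is measured by
the lag-maximized normalized cross-correlation

    C(τ) = ⟨(S(n+τ) − ⟨S⟩)(x(n) − ⟨x⟩)⟩ / sqrt(C_ss · C_xx),

with means over the measurement window and n+τ wrapped within the window
(a phase shift of the sinusoid; C(τ) is p-periodic in τ, so lags 0…p−1
suffice).  The intervention cost is the time-mean squared perturbation

    Ξ = ⟨(K·u(x(n)))² + (S(n))²⟩,

which at K = 0 reduces to α²/2 over whole drive periods.  Ensemble routines
repeat trials from independent initial conditions and summarize across
trials, the convention behind the published error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory, drive_S, evolve, rro_u
from .exceptions import DegenerateSignalError, EnsembleError
from .params import ControlParams, DriveParams, ModelParams, SimulationConfig


@dataclass(frozen=True)
class CorrelationResult:
    max_corr: float
    tau_star: int
    lags: np.ndarray
    c_profile: np.ndarray


def cross_correlation(traj: Trajectory, lags=None) -> CorrelationResult:
    """C(τ) between the drive and the orbit over ``lags`` (default 0…p−1)."""
    if lags is None:
        lags = np.arange(traj.drive.p)
    lags = np.asarray(lags, dtype=int)
    s = np.asarray(traj.s, float)
    x = np.asarray(traj.x, float)
    sc = s - s.mean()
    xc = x - x.mean()
    c_ss = float(np.mean(sc**2))
    c_xx = float(np.mean(xc**2))
    if c_ss == 0.0:
        raise DegenerateSignalError("drive is constant (C_ss = 0); need alpha > 0")
    if c_xx == 0.0:
        raise DegenerateSignalError("orbit is constant (C_xx = 0)")
    norm = np.sqrt(c_ss * c_xx)
    prof = np.array([np.mean(np.roll(sc, -int(t)) * xc) / norm for t in lags])
    i = int(np.argmax(prof))
    return CorrelationResult(max_corr=float(prof[i]), tau_star=int(lags[i]),
                             lags=lags, c_profile=prof)


def perturbation_measure(traj: Trajectory) -> float:
    """Ξ: time-mean of (K·u(x(n)))² + (S(n))² over the measurement window."""
    return float(np.mean(traj.u_applied**2 + traj.s**2))


@dataclass(frozen=True)
class EnsembleSummary:
    mean_max_corr: float
    sd_max_corr: float
    mean_xi: float
    sd_xi: float
    n_trials: int


def sample_initial_conditions(cfg: SimulationConfig, n_trials=None) -> np.ndarray:
    """Seeded per-trial initial conditions, uniform on the x0 interval.

    Each trial draws from its own substream keyed by (seed, trial index), so
    trial i's x0 never depends on how many trials or grid points surround it.
    Draws landing exactly on the fixed point at 0 are redrawn.
    """
    n = cfg.n_trials if n_trials is None else n_trials
    lo, hi = cfg.x0_interval
    out = np.empty(n)
    for t in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, t]))
        v = 0.0
        while v == 0.0:
            v = rng.uniform(lo, hi)
        out[t] = v
    return out


def trial_ensemble(m: ModelParams, c: ControlParams, d: DriveParams,
                   cfg: SimulationConfig) -> EnsembleSummary:
    """Run ``cfg.n_trials`` trajectories from fresh seeded x0 and summarize.

    Trials share the drive phase and differ only in x(0).  Per trial the
    lag-maximized correlation and Ξ are computed; means and population
    standard deviations are taken across trials.  Degenerate trials (constant
    orbit) are excluded with a warning; fewer than two valid trials is an
    error.
    """
    if cfg.n_trials < 2:
        raise EnsembleError("need n_trials >= 2")
    x0 = sample_initial_conditions(cfg)
    xs = evolve(x0, m, c, d, cfg.n_transient, cfg.n_measure)
    n = cfg.n_transient + 1 + np.arange(cfg.n_measure)
    s = drive_S(n, d)
    sc = s - s.mean()
    c_ss = float(np.mean(sc**2))
    if c_ss == 0.0:
        raise DegenerateSignalError("drive is constant; ensemble correlation undefined")
    u_sq = (c.K * rro_u(xs, c)) ** 2
    lags = np.arange(d.p)
    corrs, xis = [], []
    for t in range(cfg.n_trials):
        xc = xs[:, t] - xs[:, t].mean()
        c_xx = float(np.mean(xc**2))
        if c_xx == 0.0:
            warnings.warn(f"trial {t} degenerate (constant orbit); excluded")
            continue
        norm = np.sqrt(c_ss * c_xx)
        prof = [np.mean(np.roll(sc, -int(tau)) * xc) / norm for tau in lags]
        corrs.append(max(prof))
        xis.append(float(np.mean(u_sq[:, t]) + np.mean(s**2)))
    if len(corrs) < 2:
        raise EnsembleError("fewer than two valid trials")
    corrs = np.asarray(corrs)
    xis = np.asarray(xis)
    return EnsembleSummary(
        mean_max_corr=float(corrs.mean()), sd_max_corr=float(corrs.std()),
        mean_xi=float(xis.mean()), sd_xi=float(xis.std()),
        n_trials=len(corrs))
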