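"""Scripted experiment drivers: parameter sweeps, resonance and forcing profiles.

These reproduce the standard analyses of the controlled cortical map:

* ``run_A_sweep`` — bifurcation structure of the uncontrolled map versus the
  inhibitory weight A, with landmark detection (chaos onset, attractor-merging
  onset, periodic window).
* ``run_K_sweep`` — bifurcation structure versus the RRO feedback gain K,
  with or without the periodic drive.
* ``run_resonance`` — trial-ensemble synchronization maxτC(τ) and cost Ξ over
  a K grid for each (α, p) drive setting; locates the correlation peak
  K_peak and the condition-defined bifurcation K*.
* ``run_forced`` — the baseline comparison: drive amplitude sweep at K = 0,
  locating the smallest α whose ensemble-mean correlation exceeds a reference.
* ``run_timeseries`` — a single annotated orbit (period, hop times).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .attractors import (BifurcationRow, bifurcation_sweep, detect_hopping,
                         detect_period, merging_bifurcation_K, sweep_to_frame)
from .dynamics import Trajectory, iterate
from .exceptions import BracketingError, DegenerateSignalError, EnsembleError
from .params import ControlParams, DriveParams, ModelParams, SimulationConfig
from .sync import EnsembleSummary, trial_ensemble

DEFAULT_A_GRID = np.round(np.arange(5.0, 15.0 + 1e-9, 0.01), 10)
DEFAULT_K_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.005), 10)
#: drive periods of the healthy period-p states used throughout
DEFAULT_PERIODS = (4, 8, 16, 32)
DEFAULT_ALPHAS = (0.01, 0.15, 0.3)


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) indices of the longest contiguous True run, or None."""
    best, cur = None, None
    for i, v in enumerate(mask):
        if v:
            cur = (cur[0], i + 1) if cur else (i, i + 1)
            if best is None or cur[1] - cur[0] > best[1] - best[0]:
                best = cur
        else:
            cur = None
    return best


def sweep_landmarks(rows: list[BifurcationRow]) -> dict:
    """Chaos onset, merging onset, and periodic-window bounds from an A-sweep.

    The chaos onset is the first grid value with λ > 0, the merging onset the
    first satisfying both merging inequalities.  The periodic window is the
    longest contiguous run above the chaos onset where the orbit is
    non-chaotic (λ < 0 or a period ≤ 64 detected); smaller windows (e.g. the
    single-point one near A = 10) are reported separately.
    """
    par = np.array([r.param for r in rows])
    lam = np.array([r.lyapunov for r in rows])
    merged = np.array([r.merged for r in rows])
    periodic = np.array([(r.lyapunov < 0) or (r.period is not None) for r in rows])

    chaotic = lam > 0
    chaos_onset = float(par[np.argmax(chaotic)]) if chaotic.any() else None
    merging_onset = float(par[np.argmax(merged)]) if merged.any() else None

    window = None
    minor_windows = []
    if chaos_onset is not None:
        above = par > chaos_onset
        mask = periodic & above
        run = _longest_true_run(mask)
        if run is not None:
            window = (float(par[run[0]]), float(par[run[1] - 1]))
            i = 0
            while i < len(par):
                if mask[i] and not (run[0] <= i < run[1]):
                    j = i
                    while j + 1 < len(par) and mask[j + 1]:
                        j += 1
                    minor_windows.append((float(par[i]), float(par[j])))
                    i = j + 1
                else:
                    i += 1
    return {"chaos_onset": chaos_onset, "merging_onset": merging_onset,
            "periodic_window": window, "minor_windows": minor_windows}


def run_A_sweep(grid=None, cfg: SimulationConfig = SimulationConfig(),
                m: ModelParams | None = None,
                c: ControlParams = ControlParams(),
                d: DriveParams = DriveParams()) -> tuple[pd.DataFrame, dict]:
    """Bifurcation sweep over the inhibitory weight A at K = 0, α = 0 defaults.

    Returns the sweep table and the landmark dictionary.
    """
    grid = DEFAULT_A_GRID if grid is None else np.asarray(grid, float)
    m = m or ModelParams(A=float(grid[0]))
    rows = bifurcation_sweep("A", grid, m, c, d, cfg)
    return sweep_to_frame(rows), sweep_landmarks(rows)


def run_K_sweep(A: float, grid=None, d: DriveParams = DriveParams(),
                cfg: SimulationConfig = SimulationConfig(),
                c: ControlParams = ControlParams()) -> tuple[pd.DataFrame, dict]:
    """Bifurcation sweep over the feedback gain K at fixed A.

    With a drive present (α > 0) the summary records how far hopping
    (chaos-chaos intermittency across x_d) persists along the grid.
    """
    grid = DEFAULT_K_GRID if grid is None else np.asarray(grid, float)
    m = ModelParams(A=A)
    rows = bifurcation_sweep("K", grid, m, c, d, cfg)
    hop = np.array([r.hopping for r in rows])
    par = np.array([r.param for r in rows])
    last_hop = float(par[hop][-1]) if hop.any() else None
    try:
        k_star = merging_bifurcation_K(m, c, k_hi=float(grid[-1]))
    except BracketingError:
        k_star = None
    return sweep_to_frame(rows), {"last_hopping_K": last_hop, "K_star": k_star}


@dataclass(frozen=True)
class ResonanceProfile:
    """Ensemble synchronization versus feedback gain for one (α, p) drive."""

    A: float
    alpha: float
    p: int
    k_grid: np.ndarray
    summaries: list[EnsembleSummary]
    K_peak: float
    K_star: float | None

    def peak_summary(self) -> EnsembleSummary:
        i = int(np.argmax([s.mean_max_corr for s in self.summaries]))
        return self.summaries[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "K": self.k_grid,
            "mean_max_corr": [s.mean_max_corr for s in self.summaries],
            "sd_max_corr": [s.sd_max_corr for s in self.summaries],
            "mean_xi": [s.mean_xi for s in self.summaries],
            "sd_xi": [s.sd_xi for s in self.summaries],
            "n_trials": [s.n_trials for s in self.summaries],
        })


def run_resonance(A: float, k_grid, alpha_list: Sequence[float] = (0.15,),
                  p_list: Sequence[int] = (32,),
                  cfg: SimulationConfig = SimulationConfig(),
                  c: ControlParams = ControlParams()) -> dict[tuple[float, int], ResonanceProfile]:
    """Trial-ensemble K profiles of maxτC(τ) and Ξ for each (α, p) pair.

    Per grid point runs ``cfg.n_trials`` trials (common drive phase, fresh
    seeded x0) and records ensemble means/SDs; the profile annotates the
    correlation peak K_peak and the condition-defined merging bifurcation K*.
    """
    k_grid = np.asarray(k_grid, float)
    m = ModelParams(A=A)
    try:
        k_star = merging_bifurcation_K(m, c, k_hi=float(k_grid[-1]))
    except BracketingError:
        k_star = None
    out = {}
    for alpha in alpha_list:
        for p in p_list:
            d = DriveParams(alpha=float(alpha), p=int(p))
            summaries = [trial_ensemble(m, replace(c, K=float(K)), d, cfg)
                         for K in k_grid]
            i_peak = int(np.argmax([s.mean_max_corr for s in summaries]))
            out[(float(alpha), int(p))] = ResonanceProfile(
                A=A, alpha=float(alpha), p=int(p), k_grid=k_grid,
                summaries=summaries, K_peak=float(k_grid[i_peak]), K_star=k_star)
    return out


@dataclass(frozen=True)
class ForcedResponse:
    """Drive-amplitude sweep at K = 0 against a reference correlation level."""

    A: float
    p: int
    reference_corr: float
    alpha_grid: np.ndarray
    summaries: list[EnsembleSummary | None]  # None where the drive is degenerate
    alpha_threshold: float | None
    xi_at_threshold: float | None

    @property
    def reached(self) -> bool:
        return self.alpha_threshold is not None

    def to_frame(self) -> pd.DataFrame:
        def g(s, attr):
            return getattr(s, attr) if s is not None else np.nan
        return pd.DataFrame({
            "alpha": self.alpha_grid,
            "mean_max_corr": [g(s, "mean_max_corr") for s in self.summaries],
            "sd_max_corr": [g(s, "sd_max_corr") for s in self.summaries],
            "mean_xi": [g(s, "mean_xi") for s in self.summaries],
            "sd_xi": [g(s, "sd_xi") for s in self.summaries],
            "n_trials": [g(s, "n_trials") for s in self.summaries],
        })


def run_forced(A: float, alpha_grid, p: int, reference_corr: float,
               cfg: SimulationConfig = SimulationConfig(),
               c: ControlParams = ControlParams()) -> ForcedResponse:
    """Forced-oscillation baseline: smallest α whose ensemble-mean maxτC(τ)
    exceeds ``reference_corr`` at K = 0, and the cost Ξ paid there.

    An unreached threshold is flagged (``alpha_threshold = None``), not raised.
    """
    alpha_grid = np.asarray(alpha_grid, float)
    m = ModelParams(A=A)
    c0 = replace(c, K=0.0)
    summaries: list[EnsembleSummary | None] = []
    for alpha in alpha_grid:
        d = DriveParams(alpha=float(alpha), p=int(p))
        try:
            summaries.append(trial_ensemble(m, c0, d, cfg))
        except (DegenerateSignalError, EnsembleError):
            summaries.append(None)
    thresh = xi_at = None
    for alpha, s in zip(alpha_grid, summaries):
        if s is not None and s.mean_max_corr > reference_corr:
            thresh, xi_at = float(alpha), s.mean_xi
            break
    return ForcedResponse(A=A, p=int(p), reference_corr=float(reference_corr),
                          alpha_grid=alpha_grid, summaries=summaries,
                          alpha_threshold=thresh, xi_at_threshold=xi_at)


def run_timeseries(A: float, K: float, d: DriveParams,
                   cfg: SimulationConfig = SimulationConfig(),
                   x0: float = 0.5,
                   c: ControlParams = ControlParams()) -> tuple[Trajectory, dict]:
    """One annotated orbit: detected period, hopping verdict and hop times."""
    m = ModelParams(A=A)
    traj = iterate(m, replace(c, K=K), d, cfg, x0)
    period = detect_period(traj) if cfg.n_measure >= 256 else None
    hopping, hops = detect_hopping(traj, c.x_d)
    sgn = np.sign(traj.x - c.x_d)
    nz = np.flatnonzero(sgn != 0)
    hop_times = []
    if nz.size > 1:
        changed = nz[1:][sgn[nz[1:]] != sgn[nz[:-1]]]
        hop_times = (traj.n0 + changed).tolist()
    return traj, {"period": period, "hopping": hopping, "hops": hops,
                  "hop_times": hop_times}
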