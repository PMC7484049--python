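"""Extrema of the composite map, attractor-merging analysis, and sweeps.

Two symmetric chaotic attractors (one per sign of x) merge — enabling
chaos-chaos intermittency — when the image of the map's local extreme values
crosses the merging point x_d: with ``f_max``/``f_min`` the local maximum and
minimum VALUES of the composite map g = F + K·u, the merged condition is

    g(f_max) < x_d   and   g(f_min) > x_d.

``f_max`` is the highest point the orbit can reach on the x > x_d side, so
``g(f_max)`` is the lowest point its image can fall to; once that image drops
below x_d the orbit can cross sides.  ``g(f_max) = 0`` (for x_d = 0) is the
attractor-merging bifurcation; ``merging_bifurcation_K`` locates its root in
the feedback gain K.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import composite_deriv, composite_map, evolve, Trajectory
from .exceptions import BracketingError, StructureError
from .params import ControlParams, DriveParams, ModelParams, SimulationConfig

SEARCH_WINDOW = (-4.0, 4.0)   # orbits stay within |x| < 4 at model parameters
_N_GRID = 4001


@dataclass(frozen=True)
class ExtremaReport:
    """Local extreme values of the composite map and the merging verdict."""

    f_max: float
    f_min: float
    x_at_max: float
    x_at_min: float
    g_of_fmax: float
    g_of_fmin: float
    merged: bool


def _critical_points(m: ModelParams, c: ControlParams):
    """(x, type) pairs of interior critical points; type +1 max, −1 min."""
    lo, hi = SEARCH_WINDOW
    xs = np.linspace(lo, hi, _N_GRID)
    d = composite_deriv(xs, m, c)
    pts = []
    for i in range(_N_GRID - 1):
        if d[i] == 0.0:
            if 0 < i and np.sign(d[i - 1]) != np.sign(d[i + 1]):
                pts.append((xs[i], 1 if d[i - 1] > 0 else -1))
        elif d[i] * d[i + 1] < 0.0:
            r = brentq(lambda x: composite_deriv(x, m, c), xs[i], xs[i + 1],
                       xtol=1e-13, rtol=8.9e-16)
            pts.append((r, 1 if d[i] > 0 else -1))
    return pts


def find_map_extrema(m: ModelParams, c: ControlParams) -> ExtremaReport:
    """Locate f_max/f_min of g = F + K·u and evaluate the merging condition.

    Critical points are bracketed by sign changes of the analytic derivative
    on a dense grid over the search window and refined by Brent root-finding.
    When several local maxima exist on the x > x_d side the one with the
    largest map value wins (ties broken by smaller |x − x_d|).
    """
    pts = _critical_points(m, c)
    maxima = [(x, float(composite_map(x, m, c))) for x, t in pts if t > 0 and x > c.x_d]
    minima = [(x, float(composite_map(x, m, c))) for x, t in pts if t < 0 and x < c.x_d]
    if not maxima or not minima:
        raise StructureError(
            f"no interior extremum on both sides of x_d={c.x_d} for A={m.A}, K={c.K}")
    x_at_max, f_max = max(maxima, key=lambda t: (t[1], -abs(t[0] - c.x_d)))
    x_at_min, f_min = min(minima, key=lambda t: (t[1], abs(t[0] - c.x_d)))
    g_of_fmax = float(composite_map(f_max, m, c))
    g_of_fmin = float(composite_map(f_min, m, c))
    merged = bool(g_of_fmax < c.x_d and g_of_fmin > c.x_d)
    return ExtremaReport(f_max=f_max, f_min=f_min, x_at_max=x_at_max,
                         x_at_min=x_at_min, g_of_fmax=g_of_fmax,
                         g_of_fmin=g_of_fmin, merged=merged)


def merging_bifurcation_K(m: ModelParams, c: ControlParams, k_hi: float) -> float:
    """Gain K* at which g(f_max) crosses x_d: the attractor-merging bifurcation.

    Requires the attractors merged at K=0 (g(f_max) < x_d) and separated at
    ``k_hi``; the root is found by bracketed bisection (Brent) on the
    continuous function K ↦ g(f_max(K)) − x_d, with the extrema recomputed at
    every K.  The K of ``c`` is ignored.
    """

    def h(K: float) -> float:
        return find_map_extrema(m, replace(c, K=K)).g_of_fmax - c.x_d

    h0, h1 = h(0.0), h(k_hi)
    if not (h0 < 0.0 < h1):
        raise BracketingError(
            f"merging condition does not change sign on K in [0, {k_hi}] "
            f"(h(0)={h0:.3g}, h(k_hi)={h1:.3g})")
    return float(brentq(h, 0.0, k_hi, xtol=1e-12, rtol=8.9e-16))


def _as_states(traj) -> np.ndarray:
    return traj.x if isinstance(traj, Trajectory) else np.asarray(traj, float)


def detect_period(traj, max_period: int = 64, tol: float = 1e-6):
    """Smallest period q ≤ max_period of the orbit tail, or None if aperiodic.

    Checks |x(n+q) − x(n)| < tol for all n over the final 4·max_period
    samples.
    """
    x = _as_states(traj)
    win = 4 * max_period
    if len(x) < win:
        raise ValueError(f"need at least {win} samples to detect periods up to "
                         f"{max_period}, got {len(x)}")
    tail = x[-win:]
    for q in range(1, max_period + 1):
        if np.all(np.abs(tail[q:] - tail[:-q]) < tol):
            return q
    return None


def detect_hopping(traj, x_d: float = 0.0) -> tuple[bool, int]:
    """Whether the orbit crosses x_d, and how many sign changes occur."""
    x = _as_states(traj)
    s = np.sign(x - x_d)
    s = s[s != 0]
    hops = int(np.count_nonzero(s[1:] != s[:-1])) if len(s) > 1 else 0
    return hops > 0, hops


@dataclass(frozen=True)
class BifurcationRow:
    """One grid point of a bifurcation sweep (two-branch convention)."""

    param: float
    x_samples: np.ndarray     # post-transient states, both branches
    lyapunov: float
    g_fmax: float
    g_fmin: float
    merged: bool
    period: int | None
    hopping: bool
    hops: int


#: initial conditions of the positive/negative branch of a sweep, matching
#: the blue/red two-branch convention of the bifurcation diagrams
BRANCH_X0 = (0.5, -0.5)


def bifurcation_sweep(axis: str, grid: Sequence[float], m: ModelParams,
                      c: ControlParams, d: DriveParams,
                      cfg: SimulationConfig, n_keep: int = 50) -> list[BifurcationRow]:
    """Sweep A or K over ``grid``, one positive- and one negative-branch orbit each.

    Per grid point reports the Lyapunov exponent (orbit-mean of ln|g'|, on the
    positive branch), the merging-condition values, the detected period and
    hopping.  All orbits across the grid are evolved in one vectorized pass.
    """
    if axis not in ("A", "K"):
        raise ValueError("axis must be 'A' or 'K'")
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    npts = len(grid)
    x0 = np.tile(np.array(BRANCH_X0), npts)            # (2*npts,)
    par = np.repeat(grid, 2)
    A = par if axis == "A" else m.A
    K = par if axis == "K" else c.K
    xs = evolve(x0, m, c, d, cfg.n_transient, cfg.n_measure, A=A, K=K)

    gp = composite_deriv(xs, m, c, A=A, K=K)
    with np.errstate(divide="ignore"):
        loggp = np.log(np.abs(gp))
    lam = np.where(np.isneginf(loggp), np.nan, loggp)  # exclude critical hits
    lam = np.nanmean(lam, axis=0)

    rows = []
    for i, v in enumerate(grid):
        mi = m if axis == "K" else replace(m, A=float(v))
        ci = c if axis == "A" else replace(c, K=float(v))
        rep = find_map_extrema(mi, ci)
        pos, neg = xs[:, 2 * i], xs[:, 2 * i + 1]
        period = detect_period(pos) if cfg.n_measure >= 4 * 64 else None
        hop_p, n_p = detect_hopping(pos, ci.x_d)
        hop_n, n_n = detect_hopping(neg, ci.x_d)
        rows.append(BifurcationRow(
            param=float(v),
            x_samples=np.concatenate([pos[-n_keep:], neg[-n_keep:]]),
            lyapunov=float(lam[2 * i]),
            g_fmax=rep.g_of_fmax, g_fmin=rep.g_of_fmin, merged=rep.merged,
            period=period, hopping=bool(hop_p or hop_n), hops=n_p + n_n))
    return rows


def sweep_to_frame(rows: list[BifurcationRow]) -> pd.DataFrame:
    """Tabulate sweep rows; attractor samples are semicolon-packed."""
    return pd.DataFrame({
        "param": [r.param for r in rows],
        "x_samples": [";".join(f"{v:.17g}" for v in r.x_samples) for r in rows],
        "lambda": [r.lyapunov for r in rows],
        "g_fmax": [r.g_fmax for r in rows],
        "g_fmin": [r.g_fmin for r in rows],
        "merged": [r.merged for r in rows],
        "period": [r.period if r.period is not None else "aperiodic" for r in rows],
        "hops": [r.hops for r in rows],
    })
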