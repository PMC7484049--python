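"""The cortical return map, RRO feedback, periodic drive, and orbit iteration.

The controlled system is

    x(n+1) = F(x(n)) + K·u(x(n)) + S(n)

with the map ``F(x) = B·tanh(w2·x) − A·tanh(w1·x)``, the RRO feedback
``u(x) = −(x−x_d)·exp(−(x−x_d)²/(2σ²))`` and the drive
``S(n) = α·sin(2πn/p)``.  ``iterate`` runs the full system; the low-level
``evolve`` helper broadcasts over arrays of initial conditions and (where
needed) per-orbit values of ``A`` and ``K``, which is what makes parameter
sweeps and trial ensembles cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import NumericalInstabilityError
from .params import (ControlParams, DriveParams, ModelParams, SimulationConfig,
                     params_to_dict)

#: orbits beyond this magnitude are treated as divergent (the map itself is
#: bounded by B + A + K·σ·e^{-1/2} + α, so this only triggers on bad input)
DIVERGENCE_BOUND = 1e3


def map_F(x, m: ModelParams):
    """Uncontrolled map F(x) = B·tanh(w2·x) − A·tanh(w1·x); odd in x."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("map_F requires finite x")
    return m.B * np.tanh(m.w2 * x) - m.A * np.tanh(m.w1 * x)


def rro_u(x, c: ControlParams):
    """RRO feedback kernel u(x) = −(x−x_d)·exp(−(x−x_d)²/(2σ²)).

    Antisymmetric about ``x_d``, with extrema of magnitude σ·e^{−1/2} at
    x = x_d ± σ — i.e. the feedback acts only near the merging point.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("rro_u requires finite x")
    dx = x - c.x_d
    return -dx * np.exp(-dx * dx / (2.0 * c.sigma**2))


def drive_S(n, d: DriveParams):
    """Periodic input S(n) = α·sin(2πn/p) at integer step(s) n."""
    n = np.asarray(n, dtype=float)
    return d.alpha * np.sin(2.0 * np.pi * n / d.p)


def composite_map(x, m: ModelParams, c: ControlParams):
    """Autonomous controlled map g(x) = F(x) + K·u(x)."""
    return map_F(x, m) + c.K * rro_u(x, c)


def composite_deriv(x, m: ModelParams, c: ControlParams, A=None, K=None):
    """Analytic derivative g'(x) of the composite map.

    g'(x) = B·w2·sech²(w2·x) − A·w1·sech²(w1·x)
            + K·exp(−(x−x_d)²/(2σ²))·((x−x_d)²/σ² − 1)

    ``A`` and ``K`` may be arrays broadcasting against ``x`` (used by the
    vectorized sweep code); they default to the scalar parameter values.
    """
    x = np.asarray(x, dtype=float)
    A = m.A if A is None else np.asarray(A, dtype=float)
    K = c.K if K is None else np.asarray(K, dtype=float)
    dx = x - c.x_d
    s2 = c.sigma**2
    return (m.B * m.w2 / np.cosh(m.w2 * x) ** 2
            - A * m.w1 / np.cosh(m.w1 * x) ** 2
            + K * np.exp(-dx * dx / (2.0 * s2)) * (dx * dx / s2 - 1.0))


def evolve(x0, m: ModelParams, c: ControlParams, d: DriveParams,
           n_transient: int, n_measure: int, A=None, K=None) -> np.ndarray:
    """Iterate the controlled system, returning the recorded states.

    ``x0`` may be a scalar or an array of initial conditions evolved in
    parallel; ``A``/``K`` may be arrays of the same shape for per-orbit
    parameter values.  The drive phase counts from global step 0, transient
    included.  Returns an array of shape ``(n_measure,) + shape(x0)`` holding
    x(n) for n = n_transient+1 … n_transient+n_measure.
    """
    x = np.array(x0, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x0 must be finite")
    A = m.A if A is None else np.asarray(A, dtype=float)
    K = c.K if K is None else np.asarray(K, dtype=float)
    w1, w2, B, x_d, s2 = m.w1, m.w2, m.B, c.x_d, c.sigma**2
    n_total = n_transient + n_measure
    S = d.alpha * np.sin(2.0 * np.pi * np.arange(n_total) / d.p)
    out = np.empty((n_measure,) + x.shape, dtype=float)
    for n in range(n_total):
        dx = x - x_d
        x = (B * np.tanh(w2 * x) - A * np.tanh(w1 * x)
             - K * dx * np.exp(-dx * dx / (2.0 * s2)) + S[n])
        if n >= n_transient:
            out[n - n_transient] = x
    if not np.all(np.isfinite(out)) or np.abs(out).max() > DIVERGENCE_BOUND:
        raise NumericalInstabilityError(
            f"orbit exceeded |x| = {DIVERGENCE_BOUND:g}; parameters outside the "
            "bounded regime of the map")
    return out


@dataclass(frozen=True)
class Trajectory:
    """A recorded orbit over the measurement window.

    ``x[i]`` is the state at global step ``n0 + i``; ``s`` and ``u_applied``
    carry the matching drive values S(n) and feedback values K·u(x(n)).
    """

    x: np.ndarray
    s: np.ndarray
    u_applied: np.ndarray
    n0: int
    model: ModelParams
    control: ControlParams
    drive: DriveParams
    config: SimulationConfig

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.s) == len(self.u_applied)):
            raise ValueError("x, s, u_applied must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    def steps(self) -> np.ndarray:
        """Global step indices n of the recorded states."""
        return self.n0 + np.arange(len(self.x))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.steps(), "x": self.x, "s": self.s, "u_applied": self.u_applied})

    def save(self, path) -> None:
        """Write the orbit as CSV plus a JSON sidecar with full metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        meta = params_to_dict(self.model, self.control, self.drive, self.config)
        meta["n0"] = self.n0
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2))


def iterate(m: ModelParams, c: ControlParams, d: DriveParams,
            cfg: SimulationConfig, x0: float) -> Trajectory:
    """Run the controlled system from ``x0`` and record the measurement window.

    Applies the update rule ``n_transient + n_measure`` times; the returned
    trajectory holds the final ``n_measure`` states.  Deterministic given
    (parameters, x0).
    """
    xs = evolve(float(x0), m, c, d, cfg.n_transient, cfg.n_measure)
    n0 = cfg.n_transient + 1
    n = n0 + np.arange(cfg.n_measure)
    s = drive_S(n, d)
    u_applied = c.K * rro_u(xs, c)
    return Trajectory(x=xs, s=s, u_applied=u_applied, n0=n0,
                      model=m, control=c, drive=d, config=cfg)
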