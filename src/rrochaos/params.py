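"""Parameter containers for the cortical map, its controller, and simulations.

The model is a one-dimensional return map for the daily activity of a
frontal-cortex neural population driven by competing excitatory and
inhibitory pathways from the sensory cortex:

    x(n+1) = B·tanh(w2·x(n)) − A·tanh(w1·x(n))

``w1``/``w2`` are input weights of the inhibitory/excitatory populations and
``A``/``B`` their output weights; ``A`` is the bifurcation parameter that
moves the system between the periodic (healthy) and chaos-chaos intermittent
(bipolar-disorder-like) regimes.  The controlled system adds a
reduced-region-of-orbit (RRO) feedback term ``K·u(x)`` and a weak sinusoidal
drive ``S(n) = α·sin(2πn/p)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Synaptic weights of the frontal–sensory map.

    Defaults for ``w1``, ``w2`` and ``B`` are the published values of the
    cortical model; ``A`` (inhibitory output weight) must be supplied, as it
    is the quantity swept in every bifurcation analysis.
    """

    A: float
    w1: float = 0.2223
    w2: float = 1.487
    B: float = 5.82

    def __post_init__(self) -> None:
        for name in ("A", "w1", "w2", "B"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.w1 > 0 and self.w2 > 0 and self.B > 0, "w1, w2, B must be > 0")
        _require(self.A >= 0, "A must be >= 0")


@dataclass(frozen=True)
class ControlParams:
    """RRO feedback law u(x) = −(x−x_d)·exp(−(x−x_d)²/(2σ²)), applied as K·u.

    ``x_d`` is the merging point of the two symmetric attractors (0 for this
    point-symmetric map) and ``sigma`` sets the width of the region where the
    feedback acts; both defaults are the published choices.
    """

    K: float = 0.0
    x_d: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("K", "x_d", "sigma"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.K >= 0, "K must be >= 0")
        _require(self.sigma > 0, "sigma must be > 0")


@dataclass(frozen=True)
class DriveParams:
    """Weak periodic input S(n) = alpha·sin(2πn/p); p counted in map steps."""

    alpha: float = 0.0
    p: int = 32

    def __post_init__(self) -> None:
        _require(math.isfinite(self.alpha) and self.alpha >= 0, "alpha must be >= 0")
        _require(isinstance(self.p, int) and self.p >= 2, "p must be an integer >= 2")


@dataclass(frozen=True)
class SimulationConfig:
    """Orbit lengths, trial count and seeding for simulations.

    ``x0_interval`` is the interval the trial-ensemble sampler draws initial
    conditions from (uniform, excluding the unstable fixed point at 0); it
    matches the attractor range seen in the bifurcation diagrams.
    """

    n_transient: int = 1000
    n_measure: int = 10_000
    seed: int = 0
    n_trials: int = 10
    x0_interval: tuple[float, float] = (-2.5, 2.5)

    def __post_init__(self) -> None:
        _require(self.n_transient >= 0, "n_transient must be >= 0")
        _require(self.n_measure > 0, "n_measure must be > 0")
        _require(self.n_trials >= 1, "n_trials must be >= 1")
        lo, hi = self.x0_interval
        _require(lo < hi, "x0_interval must be a non-empty (lo, hi) pair")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["x0_interval"] = list(self.x0_interval)
        return d


def params_to_dict(model: ModelParams, control: ControlParams,
                   drive: DriveParams, config: SimulationConfig | None = None) -> dict:
    """Flatten a parameter triplet (plus optional config) for serialization."""
    out = {"model": asdict(model), "control": asdict(control), "drive": asdict(drive)}
    if config is not None:
        out["sim"] = config.to_dict()
    return out
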