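"""First-order kinetic model of vocabulary retention and anxiety.

Two uncoupled linear ODEs driven by piecewise-constant forcing:

    dV/dt = k1 * I(t) - k2 * V      (vocabulary, 0-100 score scale)
    dA/dt = k3 * S(t) - k4 * A      (anxiety, 1-5 Likert scale)

where I(t) is intervention intensity and S(t) stress, both normalized to
[0, 1] and constant within each weekly session.  On every constant-forcing
interval the exact solution is a single exponential relaxation toward the
local steady state y* = k_gain * level / k_decay:

    y(t) = y* + (y_start - y*) * exp(-k_decay * (t - t_start))

Chaining intervals gives an exact piecewise-exponential solution, which
serves as the analytic oracle for the numerical integrator.  The model state
is continuous and unclamped; clamping to instrument ranges happens only at
observation time (in the cohort simulator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "ODEParams",
    "ForcingSchedule",
    "Trajectory",
    "vocab_rate",
    "anxiety_rate",
    "closed_form",
    "closed_form_path",
    "steady_state",
]

#: rate constants reported for the study (k1, k2 in §-vocabulary units;
#: k3, k4 for anxiety), used as simulation defaults throughout the package
DEFAULT_PARAMS: "ODEParams"

Which = Literal["vocab", "anxiety"]


@dataclass(frozen=True)
class ODEParams:
    """The four rate constants of the kinetic model.

    k1: learning-gain rate (score points / week / unit intensity)
    k2: forgetting rate (1 / week)
    k3: stress-to-anxiety rate (Likert units / week / unit stress)
    k4: anxiety-decay rate (1 / week)
    """

    k1: float = 0.05
    k2: float = 0.02
    k3: float = 0.03
    k4: float = 0.04

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    def gain_decay(self, which: Which) -> tuple[float, float]:
        return (self.k1, self.k2) if which == "vocab" else (self.k3, self.k4)


DEFAULT_PARAMS = ODEParams()


@dataclass(frozen=True)
class ForcingSchedule:
    """Piecewise-constant intensity I(t) and stress S(t) on week boundaries.

    ``breakpoints`` has m+1 strictly increasing entries delimiting m
    intervals; ``I_levels`` and ``S_levels`` give the constant level on each.
    """

    breakpoints: tuple[float, ...]
    I_levels: tuple[float, ...]
    S_levels: tuple[float, ...]

    def __post_init__(self):
        bp = self.breakpoints
        if len(bp) < 2 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing, length >= 2")
        m = len(bp) - 1
        if len(self.I_levels) != m or len(self.S_levels) != m:
            raise ValueError("need exactly one I and S level per interval")
        for lv in (*self.I_levels, *self.S_levels):
            if not (0.0 <= lv <= 1.0):
                raise ValueError(f"forcing level {lv} outside [0, 1]")

    @classmethod
    def constant(cls, I: float, S: float, t0: float = 0.0, t_end: float = 12.0):
        return cls((t0, t_end), (I,), (S,))

    @classmethod
    def weekly(cls, I_levels: Sequence[float], S_levels: Sequence[float], t0: float = 0.0):
        m = len(I_levels)
        return cls(tuple(float(t0 + w) for w in range(m + 1)),
                   tuple(I_levels), tuple(S_levels))

    @property
    def t0(self) -> float:
        return self.breakpoints[0]

    @property
    def t_end(self) -> float:
        return self.breakpoints[-1]

    def level_at(self, t: float, which: Which) -> float:
        """Forcing level at time t (right-continuous; t_end maps to last piece)."""
        if not (self.t0 <= t <= self.t_end):
            raise DomainError(f"t={t} outside schedule span [{self.t0}, {self.t_end}]")
        levels = self.I_levels if which == "vocab" else self.S_levels
        idx = min(
            int(np.searchsorted(self.breakpoints, t, side="right")) - 1,
            len(levels) - 1,
        )
        return levels[max(idx, 0)]


@dataclass
class Trajectory:
    """Model-continuous V(t) and A(t) sampled on an observation grid."""

    times: np.ndarray
    V: np.ndarray
    A: np.ndarray
    V0: float
    A0: float


def vocab_rate(V: float, I: float, params: ODEParams) -> float:
    """dV/dt = k1*I - k2*V."""
    return params.k1 * I - params.k2 * V


def anxiety_rate(A: float, S: float, params: ODEParams) -> float:
    """dA/dt = k3*S - k4*A."""
    return params.k3 * S - params.k4 * A


def _relax(y_start: float, level: float, k_gain: float, k_decay: float, dt: float) -> float:
    """Exact solution of y' = k_gain*level - k_decay*y over an interval dt."""
    if k_decay == 0.0:
        return y_start + k_gain * level * dt
    y_star = k_gain * level / k_decay
    return y_star + (y_start - y_star) * math.exp(-k_decay * dt)


def closed_form(
    y0: float,
    schedule: ForcingSchedule,
    params: ODEParams,
    t: float,
    which: Which = "vocab",
) -> float:
    """Exact piecewise-exponential solution at time t.

    Chains the single-interval relaxation across every constant-forcing piece
    up to t.  This is the analytic oracle the numerical integrator is tested
    against; it is exact up to floating-point rounding.
    """
    if not (schedule.t0 <= t <= schedule.t_end):
        raise DomainError(f"t={t} outside schedule span")
    k_gain, k_decay = params.gain_decay(which)
    levels = schedule.I_levels if which == "vocab" else schedule.S_levels
    y = float(y0)
    for i, level in enumerate(levels):
        lo, hi = schedule.breakpoints[i], schedule.breakpoints[i + 1]
        if t <= lo:
            break
        y = _relax(y, level, k_gain, k_decay, min(t, hi) - lo)
    return y


def closed_form_path(
    y0: float,
    schedule: ForcingSchedule,
    params: ODEParams,
    times: Sequence[float],
    which: Which = "vocab",
) -> np.ndarray:
    """closed_form evaluated on a non-decreasing grid of times."""
    return np.array([closed_form(y0, schedule, params, float(t), which) for t in times])


def steady_state(params: ODEParams, I: float, S: float) -> tuple[float, float]:
    """Fixed point (V*, A*) under constant forcing: V* = k1*I/k2, A* = k3*S/k4."""
    if params.k2 <= 0 or params.k4 <= 0:
        raise DomainError("steady state undefined when a decay rate is zero")
    return params.k1 * I / params.k2, params.k3 * S / params.k4
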