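"""Generic explicit embedded Runge-Kutta pair engine.

An embedded pair advances the solution with a propagating weight vector of
order ``p`` while a second weight vector of order ``p_hat`` (sharing the same
stage evaluations) yields a lower-order solution; their difference estimates
the local truncation error, which drives adaptive step-size control.

The engine is tableau-generic: any explicit pair can be supplied as a
:class:`ButcherTableau`, either constructed in code or loaded from a JSON file
(``load_tableau``).  The shipped default is the canonical 7-stage
Dormand-Prince 5(4) pair with exact rational coefficients, which passes
:func:`validate_tableau` with zero violations under exact arithmetic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .errors import IntegrationError, NonConvergenceError, TableauStructureError

__all__ = [
    "ButcherTableau",
    "IntegratorConfig",
    "SolutionPath",
    "TableauViolation",
    "dormand_prince_54",
    "validate_tableau",
    "load_tableau",
    "rk_step",
    "integrate_adaptive",
    "integrate_fixed",
]

#: tolerance for numeric (float-valued) tableau identity checks
_NUMERIC_TOL = 1e-12

Number = float | Fraction


@dataclass(frozen=True)
class ButcherTableau:
    """Coefficient scheme of an explicit embedded Runge-Kutta pair.

    Coefficients may be :class:`fractions.Fraction` (validated exactly) or
    floats (validated to 1e-12).  ``b_high`` propagates the solution at order
    ``p``; ``b_low`` is the embedded order-``p_hat`` estimator.
    """

    name: str
    stages: int
    c: tuple[Number, ...]
    a: tuple[tuple[Number, ...], ...]  # full s x s lower-triangular matrix
    b_high: tuple[Number, ...]
    b_low: tuple[Number, ...]
    p: int
    p_hat: int

    def __post_init__(self):
        s = self.stages
        if len(self.c) != s or len(self.b_high) != s or len(self.b_low) != s:
            raise TableauStructureError(
                f"tableau '{self.name}': c/b_high/b_low must all have length {s}"
            )
        if len(self.a) != s or any(len(row) != s for row in self.a):
            raise TableauStructureError(
                f"tableau '{self.name}': a must be a full {s}x{s} matrix"
            )

    def as_float(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (c, a, b_high, b_low) as float ndarrays for stepping."""
        c = np.array([float(x) for x in self.c])
        a = np.array([[float(x) for x in row] for row in self.a])
        bh = np.array([float(x) for x in self.b_high])
        bl = np.array([float(x) for x in self.b_low])
        return c, a, bh, bl


@dataclass(frozen=True)
class TableauViolation:
    """One violated tableau invariant, with location and residual size."""

    code: str
    message: str
    stage: int | None = None
    residual: float = 0.0


@dataclass(frozen=True)
class IntegratorConfig:
    """Adaptive step-size control settings (time unit: weeks)."""

    rtol: float = 1e-6
    atol: float = 1e-9
    h_init: float = 0.1
    h_min: float = 1e-10
    h_max: float = 12.0
    safety: float = 0.9
    max_steps: int = 100_000

    def __post_init__(self):
        if not (0 < self.h_min <= self.h_init <= self.h_max):
            raise ValueError("need 0 < h_min <= h_init <= h_max")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if not (0 < self.safety < 1):
            raise ValueError("safety factor must lie in (0, 1)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class SolutionPath:
    """Discrete numerical solution: times, states and step-acceptance counts."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), state_dim)
    accepted_steps: int = 0
    rejected_steps: int = 0

    def state_at(self, t: float) -> np.ndarray:
        """Return the stored state at time ``t`` (must be a stored node)."""
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0, atol=1e-12))
        if idx.size == 0:
            raise KeyError(f"time {t} is not a stored solution node")
        return self.states[idx[0]]


def _fraction_or_float(x) -> Number:
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, (int, Fraction)):
        return Fraction(x)
    return float(x)


def dormand_prince_54() -> ButcherTableau:
    """The canonical Dormand-Prince 5(4) pair with exact rational coefficients."""
    F = Fraction
    c = (F(0), F(1, 5), F(3, 10), F(4, 5), F(8, 9), F(1), F(1))
    rows = [
        [],
        [F(1, 5)],
        [F(3, 40), F(9, 40)],
        [F(44, 45), F(-56, 15), F(32, 9)],
        [F(19372, 6561), F(-25360, 2187), F(64448, 6561), F(-212, 729)],
        [F(9017, 3168), F(-355, 33), F(46732, 5247), F(49, 176), F(-5103, 18656)],
        [F(35, 384), F(0), F(500, 1113), F(125, 192), F(-2187, 6784), F(11, 84)],
    ]
    a = tuple(tuple(row + [F(0)] * (7 - len(row))) for row in rows)
    b_high = (F(35, 384), F(0), F(500, 1113), F(125, 192), F(-2187, 6784), F(11, 84), F(0))
    b_low = (
        F(5179, 57600),
        F(0),
        F(7571, 16695),
        F(393, 640),
        F(-92097, 339200),
        F(187, 2100),
        F(1, 40),
    )
    return ButcherTableau("dormand-prince-5(4)", 7, c, a, b_high, b_low, p=5, p_hat=4)


def validate_tableau(tableau: ButcherTableau) -> list[TableauViolation]:
    """Check every structural invariant of an explicit embedded pair.

    Returns one :class:`TableauViolation` per violated invariant (empty list
    iff the tableau is valid).  Exact when coefficients are Fractions,
    otherwise checked to 1e-12.  A tableau whose two weight vectors are
    identical is flagged as a degenerate embedded estimator: its error
    estimate is identically zero, so the advertised order pair is
    unverifiable.
    """
    out: list[TableauViolation] = []
    s = tableau.stages
    exact = all(
        isinstance(x, Fraction)
        for x in (*tableau.c, *tableau.b_high, *tableau.b_low)
    ) and all(isinstance(x, Fraction) for row in tableau.a for x in row)
    tol = 0 if exact else _NUMERIC_TOL

    for i in range(s):
        for j in range(i, s):
            if tableau.a[i][j] != 0:
                out.append(
                    TableauViolation(
                        "not_explicit",
                        f"a[{i}][{j}] = {tableau.a[i][j]} on or above the diagonal",
                        stage=i,
                        residual=abs(float(tableau.a[i][j])),
                    )
                )

    for label, b in (("b_high", tableau.b_high), ("b_low", tableau.b_low)):
        resid = abs(float(sum(b) - 1))
        if resid > tol:
            out.append(
                TableauViolation(
                    f"sum_{label}", f"sum({label}) != 1", residual=resid
                )
            )

    for i in range(s):
        resid = abs(float(tableau.c[i] - sum(tableau.a[i][:i])))
        if resid > tol:
            out.append(
                TableauViolation(
                    "row_sum",
                    f"c[{i}] != sum of a[{i}][:]",
                    stage=i,
                    residual=resid,
                )
            )

    if tableau.p == tableau.p_hat or tableau.p < 1 or tableau.p_hat < 1:
        out.append(
            TableauViolation(
                "orders", f"need p != p_hat and both >= 1, got ({tableau.p}, {tableau.p_hat})"
            )
        )
    if all(
        abs(float(bh - bl)) <= tol
        for bh, bl in zip(tableau.b_high, tableau.b_low)
    ):
        out.append(
            TableauViolation(
                "degenerate_embedded",
                "b_low identical to b_high: error estimate is identically zero, "
                "so the order pair (p, p_hat) is unverifiable",
            )
        )
    return out


def load_tableau(path) -> ButcherTableau:
    """Load a tableau from JSON.

    Expected keys: name, stages, c, a, b_high, b_low, order_high, order_low.
    Numeric entries may be decimals or "p/q" rational strings; rational
    strings are parsed exactly so validation can run in exact arithmetic.
    """
    with open(path) as fh:
        obj = json.load(fh)
    try:
        s = int(obj["stages"])
        c = tuple(_fraction_or_float(x) for x in obj["c"])
        a_rows = [[_fraction_or_float(x) for x in row] for row in obj["a"]]
        # pad ragged lower-triangular input out to full s x s
        a = tuple(
            tuple(row + [Fraction(0)] * (s - len(row))) for row in a_rows
        )
        bh = tuple(_fraction_or_float(x) for x in obj["b_high"])
        bl = tuple(_fraction_or_float(x) for x in obj["b_low"])
        return ButcherTableau(
            str(obj.get("name", path)), s, c, a, bh, bl,
            p=int(obj["order_high"]), p_hat=int(obj["order_low"]),
        )
    except (KeyError, ValueError, ZeroDivisionError) as exc:
        raise TableauStructureError(f"malformed tableau file {path}: {exc}") from exc


def _error_norm(y, y_high, y_low, atol: float, rtol: float) -> float:
    """Hairer-style weighted RMS norm of the embedded error estimate."""
    scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_high))
    return float(np.sqrt(np.mean(((y_high - y_low) / scale) ** 2)))


def rk_step(
    f: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    y: np.ndarray,
    h: float,
    tableau: ButcherTableau,
    atol: float = 1e-9,
    rtol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One embedded step from (t, y) of size h.

    Returns ``(y_high, y_low, err_norm)`` where the two solutions use the
    propagating and embedded weights respectively and ``err_norm`` is the
    weighted RMS of their difference against ``atol + rtol*max(|y|, |y_high|)``.
    """
    if h <= 0:
        raise ValueError("step size must be positive")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    c, a, bh, bl = tableau.as_float()
    s = tableau.stages
    k = np.empty((s, y.size))
    for i in range(s):
        yi = y + h * (a[i, :i] @ k[:i]) if i else y
        ki = np.atleast_1d(np.asarray(f(t + c[i] * h, yi), dtype=float))
        if not np.all(np.isfinite(ki)):
            raise IntegrationError(
                f"non-finite derivative at t={t + c[i] * h}, stage {i}",
                t=t + c[i] * h,
                stage=i,
            )
        k[i] = ki
    y_high = y + h * (bh @ k)
    y_low = y + h * (bl @ k)
    return y_high, y_low, _error_norm(y, y_high, y_low, atol, rtol)


def integrate_adaptive(
    f: Callable[[float, np.ndarray], np.ndarray],
    t0: float,
    t_end: float,
    y0,
    tableau: ButcherTableau | None = None,
    config: IntegratorConfig | None = None,
    t_eval: Sequence[float] | None = None,
) -> SolutionPath:
    """Integrate y' = f(t, y) from t0 to t_end with adaptive step control.

    Steps are accepted when the weighted error norm is <= 1; the next step is
    ``h * safety * err**(-1/(p_hat+1))`` clamped to [0.2h, 5h] and to
    [h_min, h_max].  The path lands exactly on ``t_end`` and on every
    requested ``t_eval`` time (steps are truncated onto them — no
    interpolation), so all returned nodes are genuine solver states.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    tableau = tableau or dormand_prince_54()
    config = config or IntegratorConfig()
    y = np.atleast_1d(np.asarray(y0, dtype=float))

    targets = sorted({float(t_end), *(float(t) for t in t_eval or [])})
    if any(t <= t0 or t > t_end for t in targets):
        raise ValueError("t_eval times must lie in (t0, t_end]")

    times = [float(t0)]
    states = [y.copy()]
    t = float(t0)
    h = config.h_init
    accepted = rejected = 0
    target_idx = 0
    order_exp = -1.0 / (tableau.p_hat + 1)

    for _ in range(config.max_steps):
        if target_idx >= len(targets):
            break
        next_target = targets[target_idx]
        h_try = min(h, next_target - t)
        y_high, _, err = rk_step(f, t, y, h_try, tableau, config.atol, config.rtol)
        if err <= 1.0:
            t = t + h_try
            y = y_high
            times.append(t)
            states.append(y.copy())
            accepted += 1
            if math.isclose(t, next_target, rel_tol=0, abs_tol=1e-12):
                t = next_target
                times[-1] = t
                target_idx += 1
        else:
            rejected += 1
        factor = 5.0 if err == 0 else config.safety * err**order_exp
        h = min(max(h_try * min(max(factor, 0.2), 5.0), config.h_min), config.h_max)
        if err > 1.0 and h_try <= config.h_min * (1 + 1e-12):
            raise NonConvergenceError(
                f"step size underflow below h_min at t={t}", t_reached=t
            )
    else:
        raise NonConvergenceError(
            f"max_steps={config.max_steps} exhausted at t={t}", t_reached=t
        )

    return SolutionPath(np.array(times), np.array(states), accepted, rejected)


def integrate_fixed(
    f: Callable[[float, np.ndarray], np.ndarray],
    t0: float,
    t_end: float,
    y0,
    tableau: ButcherTableau | None = None,
    n_steps: int = 1,
) -> SolutionPath:
    """Integrate with n_steps uniform steps, propagating solution only.

    Used as the order-verification harness (global error on a smooth problem
    scales as h^p for the order-p propagator) and as the fast inner loop of
    the fitting objective, where the forcing is constant on each segment.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    tableau = tableau or dormand_prince_54()
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    h = (t_end - t0) / n_steps
    times = [float(t0)]
    states = [y.copy()]
    for i in range(n_steps):
        t = t0 + i * h
        y, _, _ = rk_step(f, t, y, h, tableau)
        times.append(t0 + (i + 1) * h)
        states.append(y.copy())
    times[-1] = float(t_end)
    return SolutionPath(np.array(times), np.array(states), accepted_steps=n_steps)
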