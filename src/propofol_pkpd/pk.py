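"""Exact solution of the linear two-compartment disposition model.

Dosing is piecewise-constant (boluses are short infusions; an
instantaneous bolus is available for analytic work).  The drug amount
vector obeys x' = A x + u(t) e1 with A the constant disposition matrix,
so the solution is computed exactly by eigen-decomposition and
superposition of per-segment step responses; a matrix-exponential
segment-chaining fallback covers ill-conditioned eigenvector bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

from .params import InvalidParameterError, PKParameters

#: Duration used to model a "10 second" IV push, minutes.
BOLUS_DURATION_MIN = 10.0 / 60.0


@dataclass(frozen=True)
class DoseEvent:
    """One constant-rate drug administration.

    ``duration == 0`` denotes an instantaneous bolus (analytic option);
    protocol boluses are represented as 10-s infusions.
    """

    start: float
    amount: float
    duration: float = BOLUS_DURATION_MIN

    def __post_init__(self) -> None:
        if self.start < 0.0:
            raise ValueError(f"dose start must be >= 0 (minutes from induction), got {self.start}")
        if self.amount < 0.0:
            raise ValueError(f"dose amount must be >= 0 mg, got {self.amount}")
        if self.duration < 0.0:
            raise ValueError(f"dose duration must be >= 0 min, got {self.duration}")
        if self.duration > 0.0 and not math.isfinite(self.amount / self.duration):
            raise ValueError("dose rate amount/duration must be finite")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        """Infusion rate in mg/min (infinite-rate boluses have duration 0)."""
        if self.duration == 0.0:
            raise ValueError("instantaneous bolus has no finite rate")
        return self.amount / self.duration


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment concentration and peripheral amount over time."""

    times: np.ndarray
    cb: np.ndarray
    peripheral: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValueError("profile times must be non-decreasing")


def micro_constants(p: PKParameters) -> dict:
    """Micro-rate constants and disposition eigenvalues of a 2-cpt model.

    Returns k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 and the two positive
    disposition (decay) constants lambda1 >= lambda2 > 0 satisfying
    lambda1 + lambda2 = k10 + k12 + k21 and lambda1*lambda2 = k10*k21.
    """
    if not isinstance(p, PKParameters):
        p = PKParameters(*p)
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    # numerically stable quadratic roots
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = (k10 * k21) / lam1
    return {"k10": k10, "k12": k12, "k21": k21, "lambda1": lam1, "lambda2": lam2}


def pk_matrix(p: PKParameters) -> np.ndarray:
    """Disposition matrix for the amount vector (A1 central, A2 peripheral)."""
    mc = micro_constants(p)
    return np.array(
        [
            [-(mc["k10"] + mc["k12"]), mc["k21"]],
            [mc["k12"], -mc["k21"]],
        ]
    )


def _validate_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted in increasing order")
    if t.size and t[0] < 0:
        raise ValueError("times must be non-negative")
    return t


def solve_linear_dosing(
    A: np.ndarray,
    events: Iterable[DoseEvent],
    times: Sequence[float],
    input_state: int = 0,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """States of x' = A x + u(t) e_input for piecewise-constant dosing.

    Returns an array of shape (n_states, n_times).  Uses superposition of
    eigen-mode step/impulse responses (exact for the linear system); falls
    back to matrix-exponential segment chaining when the eigenvector basis
    is ill-conditioned.
    """
    t = _validate_times(times)
    events = list(events)
    n = A.shape[0]
    if t.size == 0:
        return np.zeros((n, 0))

    w, V = np.linalg.eig(A)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e8:
        return _solve_expm(A, events, t, input_state, x0)

    Vinv = np.linalg.inv(V)
    c_in = Vinv[:, input_state]  # modal weights of the input direction
    y = np.zeros((n, t.size), dtype=complex)

    if x0 is not None and np.any(x0):
        y += (Vinv @ np.asarray(x0, dtype=float))[:, None] * np.exp(np.outer(w, t))

    for ev in events:
        if ev.amount == 0.0:
            continue
        if ev.duration == 0.0:
            tau = t - ev.start
            resp = np.where(tau >= 0.0, np.exp(np.outer(w, tau)), 0.0)
            y += ev.amount * c_in[:, None] * resp
        else:
            rate = ev.amount / ev.duration
            y += rate * c_in[:, None] * (_phi(w, t - ev.start) - _phi(w, t - ev.end))

    x = (V @ y).real
    return x


def _phi(w: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Modal step-response integral (exp(w*tau) - 1)/w for tau > 0, else 0."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros((w.size, tau.size), dtype=complex)
    pos = tau > 0.0
    if np.any(pos):
        tp = tau[pos]
        for k, wk in enumerate(w):
            if abs(wk) < 1e-14:
                out[k, pos] = tp
            else:
                out[k, pos] = np.expm1(wk * tp) / wk
    return out


def _solve_expm(
    A: np.ndarray,
    events: list[DoseEvent],
    t: np.ndarray,
    input_state: int,
    x0: np.ndarray | None,
) -> np.ndarray:
    """Segment-chaining fallback via the augmented matrix exponential."""
    n = A.shape[0]
    breaks = {0.0}
    for ev in events:
        breaks.add(ev.start)
        if ev.duration > 0.0:
            breaks.add(ev.end)
    breaks.update(t.tolist())
    grid = np.array(sorted(breaks))

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    out = np.zeros((n, t.size))
    # map observation times to grid indices (grid contains all of them)
    obs_ptr = 0
    order = np.argsort(t, kind="stable")

    def record(time_val: float, state: np.ndarray) -> None:
        nonlocal obs_ptr
        while obs_ptr < t.size and t[order[obs_ptr]] <= time_val + 1e-12:
            out[:, order[obs_ptr]] = state
            obs_ptr += 1

    def apply_impulses(time_val: float, state: np.ndarray) -> None:
        for ev in events:
            if ev.duration == 0.0 and abs(ev.start - time_val) < 1e-12:
                state[input_state] += ev.amount

    apply_impulses(grid[0], x)
    record(grid[0], x)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    for i in range(len(grid) - 1):
        t0, t1 = grid[i], grid[i + 1]
        rate = 0.0
        for ev in events:
            if ev.duration > 0.0 and ev.start <= t0 + 1e-12 and ev.end >= t1 - 1e-12:
                rate += ev.amount / ev.duration
        aug[input_state, n] = rate
        P = expm(aug * (t1 - t0))
        x = P[:n, :n] @ x + P[:n, n]
        apply_impulses(t1, x)
        record(t1, x)
    return out


def solve_pk(
    p: PKParameters, events: Iterable[DoseEvent], times: Sequence[float]
) -> ConcentrationProfile:
    """Central concentration Cb (mg/L) and peripheral amount (mg) at `times`.

    Exact for piecewise-constant dosing and linear in dose.
    """
    if not isinstance(p, PKParameters):
        raise InvalidParameterError("solve_pk requires a PKParameters instance")
    t = _validate_times(times)
    x = solve_linear_dosing(pk_matrix(p), events, t)
    cb = np.maximum(x[0] / p.V1, 0.0)
    periph = np.maximum(x[1], 0.0)
    return ConcentrationProfile(times=t, cb=cb, peripheral=periph)
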