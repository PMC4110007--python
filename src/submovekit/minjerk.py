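"""Closed-form minimum-jerk submovement basis functions.

A submovement is a smooth, bell-shaped movement element. Its velocity
profile per Cartesian dimension is the classic minimum-jerk pulse

    v_d(t) = (A_d / D) * 30 * tau^2 * (1 - tau)^2,   tau = (t - t0) / D

on the support [t0, t0 + D] and zero elsewhere, where ``A_d`` is the net
displacement contributed in dimension d (cm), ``t0`` the initiation time
and ``D`` the duration (s). A reach is modeled as the superposition of a
small number of such pulses, each a discrete correction to the ongoing
trajectory. Units are cm and seconds throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimum physiologically meaningful submovement duration, seconds
#: (approximate duration of a muscle-twitch force transient).
D_MIN = 0.1


class InvalidSubmovementError(ValueError):
    """Raised for submovements violating D >= D_MIN or non-finite parameters."""


@dataclass(frozen=True)
class Submovement:
    """One minimum-jerk submovement.

    Parameters
    ----------
    t0 : float
        Initiation time within the reach, seconds (>= 0).
    D : float
        Duration, seconds (>= 0.1).
    A : array-like of shape (3,)
        Net 3D displacement (Ax, Ay, Az), cm.
    """

    t0: float
    D: float
    A: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        if self.A.shape != (3,):
            raise InvalidSubmovementError(f"A must be a 3-vector, got shape {self.A.shape}")
        if not np.isfinite(self.A).all() or not np.isfinite([self.t0, self.D]).all():
            raise InvalidSubmovementError("submovement parameters must be finite")
        if self.D < D_MIN - 1e-12:
            raise InvalidSubmovementError(f"duration {self.D} s below minimum {D_MIN} s")
        if self.t0 < 0:
            raise InvalidSubmovementError(f"initiation time {self.t0} s must be >= 0")

    @property
    def t_end(self) -> float:
        return self.t0 + self.D

    def as_tuple(self) -> tuple:
        return (self.t0, self.D, float(self.A[0]), float(self.A[1]), float(self.A[2]))


@dataclass(frozen=True)
class TimeGrid:
    """Uniformly sampled time axis, seconds. Default step 0.01 s (100 Hz)."""

    samples: np.ndarray
    dt: float = 0.01

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ValueError("grid needs at least two samples")
        steps = np.diff(self.samples)
        if not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
            raise ValueError("grid must be uniform with step dt")

    @classmethod
    def regular(cls, t_end: float, dt: float = 0.01, t_start: float = 0.0) -> "TimeGrid":
        n = int(round((t_end - t_start) / dt)) + 1
        return cls(t_start + dt * np.arange(n), dt)

    def __len__(self) -> int:
        return len(self.samples)


def _tau(sub: Submovement, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized phase tau in [0, 1] and the in-support mask."""
    tau = (np.asarray(t, float) - sub.t0) / sub.D
    mask = (tau >= 0.0) & (tau <= 1.0)
    return np.clip(tau, 0.0, 1.0), mask


def minjerk_velocity(sub: Submovement, grid: TimeGrid) -> np.ndarray:
    """Velocity of one submovement on the grid, shape (n, 3), cm/s.

    Zero outside [t0, t0+D]; the trapezoidal integral over the support
    equals A per dimension to O(dt^2) since 30 * int tau^2(1-tau)^2 dtau = 1.
    """
    tau, mask = _tau(sub, grid.samples)
    shape = 30.0 * tau**2 * (1.0 - tau) ** 2 * mask
    return np.outer(shape / sub.D, sub.A)


def minjerk_displacement(sub: Submovement, grid: TimeGrid) -> np.ndarray:
    """Displacement contributed up to each sample, shape (n, 3), cm.

    Closed-form integral of the velocity pulse: A * (10 tau^3 - 15 tau^4 + 6 tau^5),
    saturating at A after the submovement ends.
    """
    tau, _ = _tau(sub, grid.samples)
    s = 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5
    return np.outer(s, sub.A)


def minjerk_acceleration(sub: Submovement, grid: TimeGrid) -> np.ndarray:
    """Acceleration, shape (n, 3), cm/s^2 (analytic derivative of the pulse)."""
    tau, mask = _tau(sub, grid.samples)
    shape = 60.0 * tau * (1.0 - tau) * (1.0 - 2.0 * tau) * mask
    return np.outer(shape / sub.D**2, sub.A)


def superpose(subs: list[Submovement], grid: TimeGrid) -> np.ndarray:
    """Summed velocity of a set of submovements, shape (n, 3), cm/s.

    Linear in the set; an empty set yields zeros.
    """
    out = np.zeros((len(grid), 3))
    for sub in subs:
        out += minjerk_velocity(sub, grid)
    return out


def superpose_acceleration(subs: list[Submovement], grid: TimeGrid) -> np.ndarray:
    out = np.zeros((len(grid), 3))
    for sub in subs:
        out += minjerk_acceleration(sub, grid)
    return out


def position_trajectory(
    subs: list[Submovement], start: np.ndarray, grid: TimeGrid
) -> np.ndarray:
    """Position on the grid, shape (n, 3), cm.

    start + the closed-form displacement of every submovement; once all
    submovements have ended this equals start + sum(A_j) exactly.
    """
    pos = np.tile(np.asarray(start, float), (len(grid), 1))
    for sub in subs:
        pos += minjerk_displacement(sub, grid)
    return pos
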