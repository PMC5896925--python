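"""6-DOF kinematic state propagation.

Translation is integrated with velocity Verlet; rotation is restricted to
the roll axis (perfect pitch/yaw stability: the roll axis is slaved to the
velocity vector) and integrated with explicit Euler.  Body axes are
recomputed from the velocity each step and then banked by the carried roll
angle, so orthonormality is maintained by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as k

__all__ = ["BirdState", "FlightForce", "step_translation", "step_roll"]


@dataclass
class BirdState:
    """Position, velocity, roll state, and derived body axes.

    ``e_x`` is the roll axis (along the velocity), ``e_y`` the lateral
    (pitch) axis, ``e_z`` the dorsoventral (yaw) axis along which lift acts.
    """

    r: np.ndarray
    v: np.ndarray
    a: np.ndarray = field(default_factory=lambda: np.zeros(3))
    Omega: float = 0.0
    omega: float = 0.0
    _ey0: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if np.linalg.norm(self.v) <= 0:
            raise ValueError("velocity must be non-zero")

    @property
    def speed(self) -> float:
        return float(np.linalg.norm(self.v))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Banked body axes (e_x, e_y, e_z)."""
        out = k.zero_bank_axes(self.v[0], self.v[1], self.v[2],
                               self._ey0[0], self._ey0[1], self._ey0[2])
        ex = np.array(out[0:3])
        ey0 = np.array(out[3:6])
        ez0 = np.array(out[6:9])
        self._ey0 = ey0
        b = k.banked_axes(self.Omega, *ey0, *ez0)
        return ex, np.array(b[0:3]), np.array(b[3:6])


@dataclass(frozen=True)
class FlightForce:
    """Aerodynamic force components in the body frame plus weight."""

    TD: float      # along e_x (N)
    L: float       # along e_z (N)
    m: float       # mass (kg), for the weight term
    g: float = 9.81

    def total(self, e_x: np.ndarray, e_z: np.ndarray) -> np.ndarray:
        return (self.TD * e_x + self.L * e_z
                - self.m * self.g * np.array([0.0, 0.0, 1.0]))


def step_translation(state: BirdState, force: FlightForce, m: float,
                     dt: float) -> BirdState:
    """Velocity-Verlet update of position and velocity.

    The aerodynamic force is evaluated once per step, at entry; the
    velocity update uses the trapezoid of the previous and current
    accelerations, which is exact for constant forces (free fall).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    e_x, _, e_z = state.axes()
    a_new = force.total(e_x, e_z) / m
    a_old = state.a if np.any(state.a) else a_new  # first step: no history
    r = state.r + state.v * dt + 0.5 * a_new * dt * dt
    v = state.v + 0.5 * (a_old + a_new) * dt
    if np.linalg.norm(v) < 1e-9:
        raise FloatingPointError("airspeed collapsed to zero")
    return BirdState(r=r, v=v, a=a_new, Omega=state.Omega,
                     omega=state.omega, _ey0=state._ey0.copy())


def step_roll(state: BirdState, M_roll: float, I_roll: float,
              dt: float) -> BirdState:
    """Explicit-Euler update of the roll angle and rate."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not I_roll > 0:
        raise ValueError("roll inertia must be positive")
    omega_dot = M_roll / I_roll
    return BirdState(r=state.r.copy(), v=state.v.copy(), a=state.a.copy(),
                     Omega=state.Omega + state.omega * dt,
                     omega=state.omega + omega_dot * dt,
                     _ey0=state._ey0.copy())
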