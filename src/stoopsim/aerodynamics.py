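"""Wingbeat-averaged aerodynamic force model and flight-performance envelopes.

The model reduces flapping flight to a quadratic relation between net
forward force (thrust minus drag) and the wingbeat-averaged lift
coefficient: flapping thrust is maximal at zero lift and falls off as
(1 - c_l^2/c_l_max^2), scaled by a muscle-torque decrement min(1, v_thresh/v)
above the torque-constraint speed.  Gliding birds trade wing area against
induced drag by retracting their wings; the optimal retraction has a closed
form, truncated by span, stall, and torque bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernel as k
from .morphology import BirdMorphology, PhysicalConstants, total_roll_inertia

__all__ = [
    "WingConfig",
    "ForceResolution",
    "PerformanceEnvelope",
    "c_torque",
    "friction_drag_coeff",
    "max_lift_gliding",
    "thrust_minus_drag",
    "optimal_glide_span",
    "resolve_forces",
    "max_roll_acceleration",
    "performance_envelope",
]


@dataclass(frozen=True)
class WingConfig:
    """Wing geometry at one instant: span sets area and aspect ratio."""

    b: float
    S_w: float
    AR: float
    flapping: bool
    f_eff: float

    @classmethod
    def at_span(cls, b: float, morph: BirdMorphology,
                flapping: bool = False) -> "WingConfig":
        if not morph.b_min <= b <= morph.b_max + 1e-12:
            raise ValueError("span outside [b_min, b_max]")
        s = morph.S_w_max * (b - morph.b_min) / (morph.b_max - morph.b_min)
        ar = b * b / s if s > 0 else float("nan")
        return cls(b=b, S_w=s, AR=ar, flapping=flapping,
                   f_eff=morph.f if flapping else 0.0)


@dataclass(frozen=True)
class ForceResolution:
    """Outcome of one lift-control decision."""

    L: float
    TD: float
    c_l: float
    wing: WingConfig
    saturated: bool


@dataclass(frozen=True)
class PerformanceEnvelope:
    """Speed-indexed peak performance curves."""

    speed: np.ndarray
    level_acceleration: np.ndarray   # m s^-2, lift constrained to weight
    dive_acceleration: np.ndarray    # m s^-2, vertical, incl. gravity
    load_factor: np.ndarray          # max lift / weight
    roll_acceleration: np.ndarray    # rad s^-2
    turning_radius: np.ndarray       # m, v^2 / max normal acceleration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "speed": self.speed,
            "level_acceleration": self.level_acceleration,
            "dive_acceleration": self.dive_acceleration,
            "load_factor": self.load_factor,
            "roll_acceleration": self.roll_acceleration,
            "turning_radius": self.turning_radius,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pvec(morph: BirdMorphology,
          consts: PhysicalConstants | None) -> np.ndarray:
    return morph.to_vector(consts or PhysicalConstants())


def c_torque(v: float, v_thresh: float) -> float:
    """Thrust decrement from the muscle torque limit, min(1, v_thresh/v)."""
    if not v > 0:
        raise ValueError("airspeed must be strictly positive")
    return k.c_torque(v, v_thresh)


def friction_drag_coeff(v: float, wing: WingConfig,
                        morph: BirdMorphology,
                        consts: PhysicalConstants | None = None) -> float:
    """Wing friction drag coefficient (Blasius laminar plate or fixed)."""
    if not v > 0:
        raise ValueError("airspeed must be strictly positive")
    if morph.friction_mode == "fixed" or wing.S_w <= 0:
        return morph.c_d_fric_ref
    c = consts or PhysicalConstants()
    chord = wing.S_w / wing.b
    re = c.rho * v * chord / c.mu_air
    return 2.0 * 1.328 / math.sqrt(re)


def max_lift_gliding(v: float, morph: BirdMorphology,
                     consts: PhysicalConstants | None = None
                     ) -> tuple[float, float]:
    """Maximum gliding lift and the span b_ml that achieves it."""
    if not v > 0:
        raise ValueError("airspeed must be strictly positive")
    return k.max_lift_gliding(v, _pvec(morph, consts))


def thrust_minus_drag(c_l: float, wing: WingConfig, v: float,
                      morph: BirdMorphology,
                      consts: PhysicalConstants | None = None) -> float:
    """Net thrust minus drag at a given wingbeat-averaged lift coefficient.

    Flapping adds the wingbeat-averaged thrust term (quadratic lift penalty,
    torque decrement); both modes subtract parasite and induced drag.
    """
    if not v > 0:
        raise ValueError("airspeed must be strictly positive")
    if abs(c_l) > morph.c_l_max:
        raise ValueError("|c_l| exceeds c_l_max")
    p = _pvec(morph, consts)
    L = 0.5 * c_l * (consts or PhysicalConstants()).rho * wing.S_w * v * v
    if wing.flapping:
        if wing.b != morph.b_max:
            raise ValueError("flapping assumes full span")
        return k.flap_td(L, v, p)
    return k.glide_td(L, wing.b, v, p)


def optimal_glide_span(L_star: float, v: float, morph: BirdMorphology,
                       consts: PhysicalConstants | None = None
                       ) -> tuple[float, bool]:
    """Drag-minimizing gliding span for a desired lift.

    Returns (span, saturated); when the demand exceeds the attainable
    gliding lift the max-lift span is returned with the saturation flag set.
    """
    if L_star < 0 or not v > 0:
        raise ValueError("need L_star >= 0 and v > 0")
    p = _pvec(morph, consts)
    l_max, b_ml = k.max_lift_gliding(v, p)
    if L_star > l_max:
        return b_ml, True
    return k.optimal_glide_span(L_star, v, p), False


def resolve_forces(L_desired: float, v: float, morph: BirdMorphology,
                   consts: PhysicalConstants | None = None,
                   chi: float = 0.0,
                   rng: np.random.Generator | None = None,
                   dcl_dt: float = 0.0) -> ForceResolution:
    """Flap-or-glide decision meeting the desired lift with maximum thrust.

    With chi > 0 the achieved lift is perturbed multiplicatively with
    magnitude proportional to chi times the rate of change of the lift
    coefficient (``dcl_dt``, held by the caller between steps); chi = 0 is
    fully deterministic.
    """
    if L_desired < 0:
        raise ValueError("L_desired must be non-negative")
    p = _pvec(morph, consts)
    L, td, mode, cl, b, sat = k.resolve_forces(L_desired, v, p)
    if chi > 0.0:
        rng = rng or np.random.default_rng()
        L = max(0.0, L * (1.0 + chi * abs(dcl_dt) * rng.uniform(-1.0, 1.0)))
    wing = WingConfig.at_span(min(b, morph.b_max), morph,
                              flapping=(mode == k.MODE_FLAP))
    return ForceResolution(L=L, TD=td, c_l=cl, wing=wing, saturated=bool(sat))


def max_roll_acceleration(v: float, morph: BirdMorphology,
                          consts: PhysicalConstants | None = None) -> float:
    """Peak roll acceleration at airspeed v.

    Antisymmetric lift of +/- half the maximum attainable lift per wing at
    quarter-span torque arm, at the max-lift span (which also maximizes
    roll acceleration), divided by the whole-body roll inertia at the
    matching retraction.
    """
    if not v > 0:
        raise ValueError("airspeed must be strictly positive")
    om_dot, _, _, _ = k.max_roll_acceleration(v, _pvec(morph, consts))
    return om_dot


def roll_torque_and_inertia(v: float, morph: BirdMorphology,
                            consts: PhysicalConstants | None = None
                            ) -> tuple[float, float, float]:
    """(max roll torque, roll inertia, roll-optimal span) at airspeed v."""
    _, m_roll, inertia, b_roll = k.max_roll_acceleration(
        v, _pvec(morph, consts))
    return m_roll, inertia, b_roll


def level_acceleration(v: float, morph: BirdMorphology,
                       consts: PhysicalConstants | None = None) -> float:
    """Best forward acceleration with lift pinned to weight (flap/glide)."""
    p = _pvec(morph, consts)
    w = morph.m_total * (consts or PhysicalConstants()).g
    _, td, _, _, _, sat = k.resolve_forces(w, v, p)
    if sat:  # weight not supportable at this speed
        return float("-inf")
    return td / morph.m_total


def dive_acceleration(v: float, morph: BirdMorphology,
                      consts: PhysicalConstants | None = None) -> float:
    """Max vertical acceleration in a zero-lift dive, gravity included."""
    c = consts or PhysicalConstants()
    p = _pvec(morph, c)
    td = max(k.flap_td(0.0, v, p), k.glide_td(0.0, morph.b_min, v, p))
    return c.g + td / morph.m_total


def max_level_speed(morph: BirdMorphology,
                    consts: PhysicalConstants | None = None,
                    bracket: tuple[float, float] = (10.0, 80.0)) -> float:
    """Largest airspeed with non-negative level acceleration."""
    return brentq(lambda v: level_acceleration(v, morph, consts), *bracket,
                  xtol=1e-6)


def min_level_speed(morph: BirdMorphology,
                    consts: PhysicalConstants | None = None,
                    v_lo: float = 1.0, v_hi: float = 30.0) -> float:
    """Smallest airspeed with non-negative level acceleration."""
    grid = np.arange(v_lo, v_hi, 0.05)
    acc = np.array([level_acceleration(v, morph, consts) for v in grid])
    idx = np.nonzero(acc >= 0)[0]
    if len(idx) == 0:
        raise ValueError("no sustainable speed in range")
    i = idx[0]
    if i == 0:
        return grid[0]
    return brentq(lambda v: level_acceleration(v, morph, consts),
                  grid[i - 1], grid[i], xtol=1e-6)


def terminal_dive_speed(morph: BirdMorphology,
                        consts: PhysicalConstants | None = None,
                        bracket: tuple[float, float] = (5.0, 300.0)) -> float:
    """Equilibrium speed of a vertical dive (dive acceleration zero)."""
    return brentq(lambda v: dive_acceleration(v, morph, consts), *bracket,
                  xtol=1e-6)


def performance_envelope(morph: BirdMorphology,
                         consts: PhysicalConstants | None = None,
                         grid: np.ndarray | None = None
                         ) -> PerformanceEnvelope:
    """Peak performance curves over an airspeed grid."""
    if grid is None:
        grid = np.linspace(2.0, 140.0, 277)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("speed grid must be non-empty")
    if not (np.all(grid > 0) and np.all(np.diff(grid) > 0)):
        raise ValueError("speed grid must be positive and increasing")
    c = consts or PhysicalConstants()
    p = morph.to_vector(c)
    w = morph.m_total * c.g
    lev = np.empty_like(grid)
    dive = np.empty_like(grid)
    lf = np.empty_like(grid)
    roll = np.empty_like(grid)
    for i, v in enumerate(grid):
        lev[i] = level_acceleration(v, morph, c)
        dive[i] = dive_acceleration(v, morph, c)
        l_glide, _ = k.max_lift_gliding(v, p)
        lf[i] = max(l_glide, morph.L0) / w
        roll[i] = k.max_roll_acceleration(v, p)[0]
    a_normal = lf * c.g
    return PerformanceEnvelope(
        speed=grid, level_acceleration=lev, dive_acceleration=dive,
        load_factor=lf, roll_acceleration=roll,
        turning_radius=grid**2 / a_normal)
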