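"""Flight control: weight support, lift resolution, and bang-bang roll.

Turns a commanded acceleration into (i) a lift demand for the flap/glide
resolver and (ii) a target bank angle reached by bang-bang roll control at
the maximum attainable roll acceleration.  Roll torque production and lift
control are decoupled: the roll-optimal span sets torque and inertia while
the lift-optimal span sets the forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel as k
from . import aerodynamics as aero
from .guidance import GuidanceCommand
from .morphology import BirdMorphology, PhysicalConstants

__all__ = ["ControlOutput", "weight_support", "roll_target",
           "bang_bang_roll"]


@dataclass(frozen=True)
class ControlOutput:
    resolution: aero.ForceResolution
    M_roll: float   # applied roll torque (N m)
    I_roll: float   # roll inertia used (kg m^2)
    gamma: float    # signed angle to the desired bank (rad)


def weight_support(a_star: GuidanceCommand | np.ndarray, g: float,
                   axes: tuple[np.ndarray, np.ndarray, np.ndarray],
                   strict_sign: bool = False) -> np.ndarray:
    """Gravity-compensated demand projected on the body (e_y, e_z) plane.

    The aerodynamic lift must supply both the commanded acceleration and
    weight support, so gravity is compensated by adding g*e_z to the
    command (``strict_sign=True`` keeps the subtracting sign convention
    instead, for comparison).  Components along the roll axis are discarded
    — forward force is handled by thrust maximization, not by the lift
    controller.  Returns the demand in body components (0, a_y, a_z).
    """
    a = a_star.a_star if isinstance(a_star, GuidanceCommand) else a_star
    e_x, e_y, e_z = axes
    gz = -g if strict_sign else g
    a_steer = np.asarray(a, dtype=float) + np.array([0.0, 0.0, gz])
    return np.array([0.0, float(a_steer @ e_y), float(a_steer @ e_z)])


def roll_target(a_projected: np.ndarray,
                axes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                ) -> float:
    """Signed bank-angle change that aligns the yaw axis with the demand.

    ``a_projected`` is the body-frame demand (0, a_y, a_z) from
    weight_support.  Magnitude follows from the cross-product formula for
    the angle between the demand and e_z; the sign is chosen so that
    rolling through the returned angle tilts e_z toward the demand.  Zero
    demand returns zero.
    """
    ay, az = float(a_projected[1]), float(a_projected[2])
    if math.hypot(ay, az) < 1e-12:
        return 0.0
    return math.atan2(-ay, az)


def bang_bang_roll(gamma: float, omega: float, max_accel: float) -> float:
    """Sign (+1/-1/0) of the roll torque under minimum-time bang-bang.

    Accelerate toward the target unless the current rate already points at
    the target and the stopping distance omega^2 / (2 max_accel) exceeds
    the remaining angle, in which case decelerate."""
    if not max_accel > 0:
        raise ValueError("max_accel must be positive")
    return k.bang_bang_sign(gamma, omega, max_accel)


def resolve(a_star: GuidanceCommand | np.ndarray,
            v: np.ndarray,
            axes: tuple[np.ndarray, np.ndarray, np.ndarray],
            omega: float,
            morph: BirdMorphology,
            consts: PhysicalConstants | None = None,
            chi: float = 0.0,
            rng: np.random.Generator | None = None,
            dcl_dt: float = 0.0) -> ControlOutput:
    """Full control pass: demand -> (forces, roll torque) for one step."""
    c = consts or PhysicalConstants()
    a_proj = weight_support(a_star, c.g, axes)
    gamma = roll_target(a_proj)
    speed = float(np.linalg.norm(v))
    m_max, inertia, _ = aero.roll_torque_and_inertia(speed, morph, c)
    om_dot_max = m_max / inertia
    sgn = bang_bang_roll(gamma, omega, om_dot_max)
    l_star = morph.m_total * float(np.linalg.norm(a_proj))
    res = aero.resolve_forces(l_star, speed, morph, c, chi=chi, rng=rng,
                              dcl_dt=dcl_dt)
    return ControlOutput(resolution=res, M_roll=sgn * m_max,
                         I_roll=inertia, gamma=gamma)
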