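"""Sensing and pure proportional navigation (PPN).

The attacker's only sensory input is the line-of-sight (LOS) direction to
the target, measured with a bounded angular error and sampled every tau
seconds.  Differencing two successive noisy measurements gives a held
estimate of the LOS angular rate; PPN commands an acceleration
a* = N * lambda_dot x v, perpendicular to the attacker's velocity by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as k

__all__ = ["VisionState", "GuidanceCommand", "measure_los", "los_rate",
           "ppn_command"]

DEFAULT_XI = 0.007   # visual error bound, rad (minimum perceivable motion
                     # of ~8 deg/s over one 50 ms differencing interval)
DEFAULT_TAU = 0.050  # sample-and-hold / differencing interval, s


@dataclass(frozen=True)
class GuidanceCommand:
    a_star: np.ndarray  # commanded acceleration, inertial frame (m s^-2)


@dataclass
class VisionState:
    """Sample-and-hold vision: keeps the last measurement and the held
    LOS-rate estimate.  ``error_model`` selects how the angular error is
    distributed: "circular" (uniform magnitude, uniform direction on the
    circle around the true LOS) or "solid_angle" (uniform over the error
    cone)."""

    xi: float = DEFAULT_XI
    tau: float = DEFAULT_TAU
    error_model: str = "circular"
    lambda_dot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    _r_prev: np.ndarray | None = None
    _t_prev: float | None = None

    def observe(self, r_d: np.ndarray, t: float,
                rng: np.random.Generator) -> np.ndarray:
        """Ingest one (noisy) sighting at time t; update the held rate."""
        r_hat = measure_los(np.asarray(r_d, float), self.xi, rng,
                            self.error_model)
        if self._r_prev is not None and t > self._t_prev:
            self.lambda_dot = los_rate(r_hat, self._r_prev,
                                       t - self._t_prev)
        self._r_prev = r_hat
        self._t_prev = t
        return r_hat


def measure_los(r_d: np.ndarray, xi: float, rng: np.random.Generator,
                error_model: str = "circular") -> np.ndarray:
    """Measured LOS vector: truth plus a range-scaled angular error.

    Error magnitude ~ U(0, xi) rad; direction uniform on the circle
    perpendicular to the true LOS ("circular") or uniform in solid angle
    over the xi-cone ("solid_angle")."""
    r_d = np.asarray(r_d, dtype=float)
    rn = np.linalg.norm(r_d)
    if rn <= 0:
        raise ValueError("relative position must be non-zero")
    if xi <= 0:
        return r_d.copy()
    u = r_d / rn
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    if error_model == "circular":
        mag = rng.uniform(0.0, xi)
    elif error_model == "solid_angle":
        mag = xi * np.sqrt(rng.uniform())  # small-angle area weighting
    else:
        raise ValueError("unknown error model")
    ang = rng.uniform(0.0, 2.0 * np.pi)
    eps = mag * (np.cos(ang) * e1 + np.sin(ang) * e2)
    return r_d + eps * rn


def los_rate(r_hat: np.ndarray, r_hat_prev: np.ndarray,
             dt_sample: float) -> np.ndarray:
    """LOS angular rate lambda_dot = r x v_rel / |r|^2 with the relative
    velocity estimated by finite differencing."""
    if not dt_sample > 0:
        raise ValueError("differencing time must be positive")
    r = np.asarray(r_hat, dtype=float)
    return np.array(k.los_rate(r[0], r[1], r[2],
                               r_hat_prev[0], r_hat_prev[1], r_hat_prev[2],
                               dt_sample))


def ppn_command(lambda_dot: np.ndarray, v_attacker: np.ndarray,
                N: float) -> GuidanceCommand:
    """Pure proportional navigation: a* = N * lambda_dot x v."""
    if not N > 0:
        raise ValueError("navigation constant must be positive")
    return GuidanceCommand(
        a_star=N * np.cross(np.asarray(lambda_dot, float),
                            np.asarray(v_attacker, float)))
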