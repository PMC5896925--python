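"""Model-prey forcing functions: straight flight, smooth and non-smooth
(jinking) maneuvers.

The prey is not reactive; its guidance is an open-loop forcing function
scaled by the normal acceleration attainable at its current airspeed, with
a restoring vertical term that keeps it within roughly +/- 20 m of its
starting altitude.  The constants c1..c9 were calibrated (externally) to
maximize maneuvering accelerations subject to isotropy and the altitude
band; they are model settings here, not free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as k
from .guidance import GuidanceCommand
from .morphology import BirdMorphology, PhysicalConstants

__all__ = ["PreyForcingParams", "straight_command", "smooth_command",
           "nonsmooth_command", "attainable_normal_acceleration",
           "DEFAULT_C"]

MODES = ("straight", "smooth", "nonsmooth")

# c1..c9 (c9 in degrees): amplitude/frequency/shape of the smooth forcing,
# altitude gains, and the switching probability/blend of the jinking mode.
DEFAULT_C = (0.7, 3.5, 0.13, 1.5, 0.008, 0.99, 1.6, 0.1, 20.0)


@dataclass
class PreyForcingParams:
    mode: str = "nonsmooth"
    c: tuple = DEFAULT_C
    kappa_ref: float = 0.0              # starting altitude (m)
    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    heading: np.ndarray | None = None   # straight-mode target direction

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if len(self.c) != 9:
            raise ValueError("expected 9 forcing constants")

    def randomize(self, rng: np.random.Generator) -> None:
        """Draw the straight-mode heading and the initial jink direction."""
        az = rng.uniform(0, 2 * np.pi)
        el = np.deg2rad(rng.uniform(-2.5, 2.5))
        self.heading = np.array([np.cos(el) * np.cos(az),
                                 np.cos(el) * np.sin(az), np.sin(el)])
        az = rng.uniform(0, 2 * np.pi)
        el = np.deg2rad(rng.uniform(-self.c[8], self.c[8]))
        self.q = np.array([np.cos(el) * np.cos(az),
                           np.cos(el) * np.sin(az), np.sin(el)])


def attainable_normal_acceleration(v: float, morph: BirdMorphology,
                                   consts: PhysicalConstants | None = None
                                   ) -> float:
    """Normal acceleration attainable at airspeed v (flap or glide)."""
    return k.prey_amax(v, morph.to_vector(consts or PhysicalConstants()))


def straight_command(v: np.ndarray, params: PreyForcingParams,
                     morph: BirdMorphology,
                     consts: PhysicalConstants | None = None
                     ) -> GuidanceCommand:
    """Turn toward a fixed near-horizontal heading, then fly straight.

    The commanded magnitude is capped so that, combined with gravity
    compensation, the total stays within the attainable normal
    acceleration; it tapers to zero as the velocity aligns."""
    if params.heading is None:
        raise ValueError("heading not initialized; call randomize() first")
    s = np.zeros(16)
    s[3:6] = v
    out = k.straight_forcing(s, morph.to_vector(consts or PhysicalConstants()),
                             params.heading[0], params.heading[1],
                             params.heading[2])
    return GuidanceCommand(a_star=np.array(out))


def smooth_command(t: float, v: np.ndarray, altitude: float,
                   params: PreyForcingParams, morph: BirdMorphology,
                   consts: PhysicalConstants | None = None
                   ) -> GuidanceCommand:
    """Harmonic centripetal demand along the horizontal normal to the
    velocity, plus the altitude-restoring vertical term."""
    s = np.zeros(16)
    s[3:6] = v
    c = params.c
    out = k.smooth_forcing(t, s, morph.to_vector(consts or PhysicalConstants()),
                           c[0], c[1], c[2], c[3],
                           altitude - params.kappa_ref)
    return GuidanceCommand(a_star=np.array(out))


def nonsmooth_command(v: np.ndarray, altitude: float,
                      params: PreyForcingParams, morph: BirdMorphology,
                      rng: np.random.Generator,
                      consts: PhysicalConstants | None = None,
                      ) -> GuidanceCommand:
    """Stepwise random-direction demand (jinking).

    Each step, with probability c5, the direction blends toward a fresh
    random unit vector (uniform azimuth, elevation within +/- c9 degrees)
    and is renormalized; the command magnitude is c6 times the attainable
    normal acceleration."""
    c = params.c
    q = params.q
    if rng.uniform() < c[4]:
        az = rng.uniform(0, 2 * np.pi)
        el = np.deg2rad(rng.uniform(-c[8], c[8]))
        qq = np.array([np.cos(el) * np.cos(az),
                       np.cos(el) * np.sin(az), np.sin(el)])
        q = c[7] * q + (1 - c[7]) * qq
        q /= np.linalg.norm(q)
        params.q = q
    amax = attainable_normal_acceleration(float(np.linalg.norm(v)), morph,
                                          consts)
    a = q * c[5] * amax
    a = a + np.array([0.0, 0.0, -c[6] * (altitude - params.kappa_ref)])
    return GuidanceCommand(a_star=a)


def free_flight_stats(morph: BirdMorphology, mode: str, duration: float,
                      dt: float, seed: int, v0: float = 11.0,
                      consts: PhysicalConstants | None = None,
                      log_every: int = 10) -> dict:
    """Run the prey alone for ``duration`` seconds and summarize.

    Returns mean load factor, mean |roll acceleration| and |roll rate|,
    the altitude excursion, and the logged horizontal command directions
    (for isotropy checks)."""
    p = morph.to_vector(consts or PhysicalConstants())
    n_steps = int(round(duration / dt))
    n_log = n_steps // log_every + 1
    buf = np.zeros((n_log, 8))
    mode_code = MODES.index(mode)
    n = k.run_prey_free(p, mode_code, duration, dt, seed,
                        np.array(DEFAULT_C), v0, log_every, buf)
    buf = buf[:n]
    return {
        "mean_load_factor": float(buf[:, 2].mean()),
        "mean_abs_roll_accel": float(buf[:, 3].mean()),
        "mean_abs_roll_rate": float(np.abs(buf[:, 7]).mean()),
        "altitude_min": float(buf[:, 1].min()),
        "altitude_max": float(buf[:, 1].max()),
        "mean_speed": float(buf[:, 6].mean()),
        "command_xy": buf[:, 4:6].copy(),
        "t": buf[:, 0].copy(),
    }


def verify_calibration(morph: BirdMorphology, duration: float = 100.0,
                       dt: float = 1e-3, seed: int = 0) -> dict:
    """Report the calibration constraints for both maneuver modes: mean
    roll rate and roll acceleration (the bound is stated ambiguously in
    rate vs acceleration units, so both are reported), altitude bounds,
    and a horizontal-isotropy statistic (resultant length of the command
    directions; near 0 = isotropic)."""
    out = {}
    for mode in ("smooth", "nonsmooth"):
        s = free_flight_stats(morph, mode, duration, dt, seed)
        xy = s["command_xy"]
        norms = np.linalg.norm(xy, axis=1)
        ok = norms > 1e-9
        dirs = xy[ok] / norms[ok, None]
        resultant = float(np.linalg.norm(dirs.mean(axis=0))) if ok.any() else 1.0
        out[mode] = {
            "mean_load_factor": s["mean_load_factor"],
            "mean_abs_roll_accel_rad_s2": s["mean_abs_roll_accel"],
            "mean_abs_roll_rate_rad_s": s["mean_abs_roll_rate"],
            "altitude_band_m": (s["altitude_min"], s["altitude_max"]),
            "horizontal_resultant": resultant,
        }
    return out
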