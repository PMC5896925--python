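"""One falcon-versus-prey encounter: initialization, stepping, termination.

The prey starts at the origin with a random orientation; the falcon starts
offset horizontally and vertically, flying straight at the prey.  The
encounter ends with a catch (closest approach within the catch radius), an
unrecoverable near-miss (the falcon passed close, then lost the prey into
the blind cone behind it), or a timeout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel as k
from .morphology import BirdMorphology, PhysicalConstants, FALCON, STARLING
from .prey import DEFAULT_C, MODES

__all__ = ["EngagementConfig", "EngagementResult", "run", "initialize"]

OUTCOME_NAMES = {k.OUT_CATCH: "catch", k.OUT_NEAR_MISS: "near_miss_fail",
                 k.OUT_TIMEOUT: "timeout", k.OUT_ERROR: "error"}


@dataclass(frozen=True)
class EngagementConfig:
    """Attack strategy plus sensing/control assumptions and termination
    rules.  Defaults are the baseline study conditions."""

    N: float = 3.0                 # navigation constant
    altitude: float = 800.0        # initial falcon height above prey (m)
    horiz_dist: float = 600.0      # initial horizontal separation (m)
    tau: float = 0.050             # vision sample/differencing interval (s)
    xi: float = 0.007              # visual error bound (rad)
    chi: float = 0.0               # control error gain
    prey_mode: str = "nonsmooth"   # straight | smooth | nonsmooth
    dt: float = 1e-4               # integration step (s)
    catch_radius: float = 0.2      # m
    near_miss_radius: float = 5.0  # m
    blind_cone_half_angle: float = 45.0  # deg, cone behind the falcon
    timeout: float = 40.0          # s
    v0_prey: float = 11.0          # m/s (minimum cost of transport)
    v0_falcon: float = 16.0        # m/s
    seed: int = 0
    vision_noise: str = "rate"     # "rate": per-measurement bound scales
                                   # with the differencing interval (fixed
                                   # retinal rate noise xi / tau_ref);
                                   # "fixed": bound is xi regardless of tau
    tau_ref: float = 0.050         # reference interval at which xi is quoted
    load_factor_cap: float = float("inf")
    roll_accel_cap: float = float("inf")
    strict_weight_sign: bool = False
    forcing_constants: tuple = DEFAULT_C

    def __post_init__(self) -> None:
        if self.prey_mode not in MODES:
            raise ValueError(f"prey_mode must be one of {MODES}")
        if not (self.dt > 0 and self.timeout > 0 and self.tau >= 0):
            raise ValueError("dt, timeout must be positive; tau >= 0")

    def replace(self, **kw) -> "EngagementConfig":
        return replace(self, **kw)


@dataclass
class EngagementResult:
    outcome: str                  # catch | near_miss_fail | timeout | error
    t_end: float                  # s
    intercept_speed: float        # falcon speed at termination (m/s)
    min_distance: float           # closest approach (m)
    n_steps: int
    config: EngagementConfig
    trajectory: pd.DataFrame | None = None

    @property
    def caught(self) -> bool:
        return self.outcome == "catch"

    def to_json(self, path: str | Path) -> None:
        d = {key: val for key, val in asdict(self).items()
             if key != "trajectory"}
        Path(path).write_text(json.dumps(d, indent=2, default=float))

    def trajectory_to_csv(self, path: str | Path) -> None:
        if self.trajectory is None:
            raise ValueError("engagement was run without logging")
        self.trajectory.to_csv(path, index=False)


def initialize(config: EngagementConfig,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Initial (falcon, prey) kinematic states, mirroring the kernel setup.

    Each state is the packed kernel array: r[0:3], v[3:6].  The prey sits
    at the origin with a uniformly random flight direction at v0_prey; the
    falcon is offset by (horiz_dist, 0, altitude) flying straight at the
    prey at v0_falcon with its lateral axis horizontal."""
    rng = rng or np.random.default_rng(config.seed)
    az = rng.uniform(0, 2 * np.pi)
    cz = rng.uniform(-1, 1)
    sz = np.sqrt(1 - cz * cz)
    prey = k.init_bird_state(0.0, 0.0, 0.0,
                             config.v0_prey * sz * np.cos(az),
                             config.v0_prey * sz * np.sin(az),
                             config.v0_prey * cz)
    r_f = np.array([config.horiz_dist, 0.0, config.altitude])
    rn = np.linalg.norm(r_f)
    v_f = -config.v0_falcon * r_f / rn if rn > 0 else \
        np.array([config.v0_falcon, 0.0, 0.0])
    falcon = k.init_bird_state(r_f[0], r_f[1], r_f[2], v_f[0], v_f[1], v_f[2])
    return falcon, prey


def run(config: EngagementConfig,
        falcon: BirdMorphology = FALCON,
        prey_morph: BirdMorphology = STARLING,
        consts: PhysicalConstants | None = None,
        log_every: int = 0) -> EngagementResult:
    """Simulate one engagement; deterministic given (config, seed).

    ``log_every`` > 0 records a decimated trajectory (one row per that many
    steps)."""
    c = consts or PhysicalConstants()
    pf = falcon.to_vector(c)
    pp = prey_morph.to_vector(c)
    n_steps = int(round(config.timeout / config.dt))
    if log_every > 0:
        buf = np.zeros((n_steps // log_every + 2, 12))
    else:
        buf = np.zeros((1, 12))
    mode_code = MODES.index(config.prey_mode)
    cone_cos = np.cos(np.deg2rad(config.blind_cone_half_angle))
    if config.vision_noise == "rate":
        xi_eff = config.xi * max(config.tau, config.dt) / config.tau_ref
    elif config.vision_noise == "fixed":
        xi_eff = config.xi
    else:
        raise ValueError("vision_noise must be 'rate' or 'fixed'")
    out = k.run_engagement(
        pf, pp, config.N, config.altitude, config.horiz_dist,
        config.tau, xi_eff, config.chi, mode_code, config.dt,
        config.timeout, config.catch_radius, config.near_miss_radius,
        cone_cos, config.v0_prey, config.v0_falcon,
        int(config.seed) % (2**31 - 1),
        np.asarray(config.forcing_constants, dtype=float),
        config.load_factor_cap, config.roll_accel_cap,
        config.strict_weight_sign, log_every, buf)
    outcome, t_end, speed, min_dist, steps, n_logged = out
    if outcome == k.OUT_ERROR:
        raise FloatingPointError(
            f"engagement diverged at t={t_end:.4f}s (config={config})")
    traj = None
    if log_every > 0:
        traj = pd.DataFrame(
            buf[:n_logged],
            columns=["t", "x_falcon", "y_falcon", "z_falcon",
                     "x_prey", "y_prey", "z_prey", "speed_falcon",
                     "speed_prey", "roll_falcon", "distance", "_reserved"])
        traj = traj.drop(columns="_reserved")
    return EngagementResult(outcome=OUTCOME_NAMES[outcome], t_end=t_end,
                            intercept_speed=speed, min_distance=min_dist,
                            n_steps=steps, config=config, trajectory=traj)
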