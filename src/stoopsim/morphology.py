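"""Physical constants and species flight morphology.

The simulator describes each bird by a small vector of empirically measurable
morphological parameters (wingbeat frequency, span, masses, inertias, drag
coefficients, ...).  Measured values shipped with the package (peregrine
falcon and common starling) are authoritative; allometric scaling laws are
provided only as fallbacks for species without direct measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "PhysicalConstants",
    "BirdMorphology",
    "body_roll_inertia",
    "wing_inertia_about_cg",
    "total_roll_inertia",
    "load_species",
    "FALCON",
    "STARLING",
]

# Allometric constants: body width w_b = W_B_COEF * m_b**W_B_EXP, and the
# roll inertia of a 1 kg, 1 m wide reference body.
W_B_COEF = 0.098
W_B_EXP = 0.35
I_B0 = 0.1346717


@dataclass(frozen=True)
class PhysicalConstants:
    """Ambient air and gravity (ISA sea level defaults)."""

    rho: float = 1.225       # air density, kg m^-3
    g: float = 9.81          # gravitational acceleration, m s^-2
    mu_air: float = 1.81e-5  # dynamic viscosity of air, Pa s

    def __post_init__(self) -> None:
        for name in ("rho", "g", "mu_air"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def body_roll_inertia(m_b: float) -> float:
    """Allometric estimate of the body's roll-axis moment of inertia.

    Scales a single calibration bird (0.293 kg, I_b = 1.6855e-4 kg m^2) by
    body width squared times mass, with width itself an allometric function
    of mass.  The printed calibration constant does not exactly round-trip
    the calibration bird (a few percent gap); shipped species therefore
    carry measured inertias and this function is only a fallback.
    """
    if not m_b > 0:
        raise ValueError("body mass must be strictly positive")
    return I_B0 * W_B_COEF**2 * m_b**1.70


def wing_inertia_about_cg(morph: "BirdMorphology", phi: float) -> float:
    """Moment of inertia of one wing about the bird's center of mass.

    ``phi`` is the wing retraction fraction (current wing length over full
    wing length); the shoulder-referenced inertia scales with ``phi**2``,
    the parallel-axis term with the (fixed) shoulder-to-CG offset, and the
    cross term with ``phi``.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("retraction fraction phi must lie in [0, 1]")
    m_b, m_w = morph.m_b, morph.m_w
    return (
        morph.I_wing * phi**2
        + 0.25 * W_B_COEF**2 * m_b**0.70 * m_w
        + W_B_COEF * m_b**W_B_EXP * morph.J * phi
    )


def total_roll_inertia(morph: "BirdMorphology", phi: float) -> float:
    """Whole-body roll moment of inertia at retraction fraction ``phi``."""
    return morph.I_b + 2.0 * wing_inertia_about_cg(morph, phi)


@dataclass(frozen=True)
class BirdMorphology:
    """Per-species physical parameters plus derived inertial quantities.

    ``m_total`` defaults to body plus both wings; ``L0``, the maximum lift
    at full span, follows the allometric muscle-torque rule L0 = 1.7 m g.
    """

    species: str
    f: float          # max wingbeat frequency (Hz)
    l_w: float        # wing length (m)
    b_max: float      # max wing span (m)
    m_b: float        # body mass (kg)
    m_w: float        # single-wing mass (kg)
    I_b: float        # body roll inertia (kg m^2)
    I_wing: float     # wing inertia about shoulder (kg m^2)
    J: float          # wing mass-moment sum (kg m)
    S_w_max: float    # wing area at full span (m^2)
    AR_max: float     # aspect ratio at full span
    theta: float      # angular flapping amplitude (rad)
    S_b: float        # frontal body area (m^2)
    c_d_body: float   # body drag coefficient
    c_d_fric_ref: float  # reference wing friction drag coefficient
    v_thresh: float   # torque-constraint speed (m/s)
    c_l_max: float    # max steady lift coefficient
    b_min: float | None = None        # min wing span (m); default 0.2 b_max
    body_mass_only: bool = False      # use m_b instead of m_b + 2 m_w
    friction_mode: str = "blasius"    # "blasius" (Re-dependent) or "fixed"
    g: float = 9.81   # used for L0; keep consistent with PhysicalConstants

    def __post_init__(self) -> None:
        if self.b_min is None:
            object.__setattr__(self, "b_min", 0.2 * self.b_max)
        if not self.b_min < self.b_max:
            raise ValueError("b_min must be smaller than b_max")
        for name in ("f", "l_w", "m_b", "m_w", "I_b", "I_wing", "J",
                     "S_w_max", "AR_max", "theta", "S_b", "v_thresh",
                     "c_l_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.friction_mode not in ("blasius", "fixed"):
            raise ValueError("friction_mode must be 'blasius' or 'fixed'")

    @property
    def m_total(self) -> float:
        return self.m_b if self.body_mass_only else self.m_b + 2.0 * self.m_w

    @property
    def L0(self) -> float:
        """Maximum lift at full span (muscle torque limit), 1.7 m g."""
        return 1.7 * self.m_total * self.g

    @property
    def weight(self) -> float:
        return self.m_total * self.g

    def with_options(self, **kwargs) -> "BirdMorphology":
        return replace(self, **kwargs)

    # ---- packed representation used by the numerical kernels ----

    def to_vector(self, consts: PhysicalConstants | None = None) -> np.ndarray:
        from . import _kernel as k

        c = consts or PhysicalConstants()
        vec = np.empty(k.PVEC_LEN, dtype=np.float64)
        vec[k.IDX_F] = self.f
        vec[k.IDX_LW] = self.l_w
        vec[k.IDX_BMAX] = self.b_max
        vec[k.IDX_BMIN] = self.b_min
        vec[k.IDX_M] = self.m_total
        vec[k.IDX_SWMAX] = self.S_w_max
        vec[k.IDX_ARMAX] = self.AR_max
        vec[k.IDX_THETA] = self.theta
        vec[k.IDX_SB] = self.S_b
        vec[k.IDX_CDBODY] = self.c_d_body
        vec[k.IDX_CDFRIC] = self.c_d_fric_ref
        vec[k.IDX_VTH] = self.v_thresh
        vec[k.IDX_CLMAX] = self.c_l_max
        vec[k.IDX_L0] = self.L0
        vec[k.IDX_IB] = self.I_b
        vec[k.IDX_IWING] = self.I_wing
        vec[k.IDX_MB] = self.m_b
        vec[k.IDX_MW] = self.m_w
        vec[k.IDX_J] = self.J
        vec[k.IDX_FRICMODE] = 0.0 if self.friction_mode == "blasius" else 1.0
        vec[k.IDX_RHO] = c.rho
        vec[k.IDX_G] = c.g
        vec[k.IDX_MU] = c.mu_air
        return vec

    # ---- config I/O ----

    @classmethod
    def from_mapping(cls, data: Mapping, **overrides) -> "BirdMorphology":
        d = dict(data)
        d.update(overrides)
        theta = d.pop("theta", None)
        if theta is None:
            theta = d.pop("theta_over_pi") * math.pi
        else:
            d.pop("theta_over_pi", None)
        known = {
            "species", "f", "l_w", "b_max", "b_min", "m_b", "m_w", "I_b",
            "I_wing", "J", "S_w_max", "AR_max", "S_b", "c_d_body",
            "c_d_fric_ref", "v_thresh", "c_l_max", "body_mass_only",
            "friction_mode", "g",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown morphology fields: {sorted(unknown)}")
        if "I_b" not in d:  # allometric fallback for sparse configs
            d["I_b"] = body_roll_inertia(d["m_b"])
        return cls(theta=theta, **d)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "BirdMorphology":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh), **overrides)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "species": self.species, "f": self.f, "l_w": self.l_w,
            "b_max": self.b_max, "b_min": self.b_min, "m_b": self.m_b,
            "m_w": self.m_w, "I_b": self.I_b, "I_wing": self.I_wing,
            "J": self.J, "S_w_max": self.S_w_max, "AR_max": self.AR_max,
            "theta": self.theta, "S_b": self.S_b, "c_d_body": self.c_d_body,
            "c_d_fric_ref": self.c_d_fric_ref, "v_thresh": self.v_thresh,
            "c_l_max": self.c_l_max,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_species(name: str, **overrides) -> BirdMorphology:
    """Load a bundled species config ("falcon" or "starling")."""
    ref = resources.files("stoopsim.data") / f"{name}.yaml"
    with ref.open() as fh:
        return BirdMorphology.from_mapping(yaml.safe_load(fh), **overrides)


FALCON = load_species("falcon")
STARLING = load_species("starling")
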