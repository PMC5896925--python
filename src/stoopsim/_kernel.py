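"""Jitted numerical core shared by every module.

All physics is written once here as scalar float64 functions and compiled
with numba; the public modules (aerodynamics, control, engagement, ...) are
thin typed wrappers over these kernels, so the per-step engagement loop and
the module-level API cannot drift apart.

Set the environment variable NUMBA_DISABLE_JIT=1 to run the same code in
pure Python (useful when debugging).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

# ---------------------------------------------------------------------------
# Packed parameter vector layout (morphology + ambient constants)
# ---------------------------------------------------------------------------
IDX_F = 0        # max wingbeat frequency (Hz)
IDX_LW = 1       # wing length (m)
IDX_BMAX = 2     # max span (m)
IDX_BMIN = 3     # min span (m)
IDX_M = 4        # total mass (kg)
IDX_SWMAX = 5    # wing area at full span (m^2)
IDX_ARMAX = 6    # aspect ratio at full span
IDX_THETA = 7    # flapping amplitude (rad)
IDX_SB = 8       # frontal body area (m^2)
IDX_CDBODY = 9   # body drag coefficient
IDX_CDFRIC = 10  # reference wing friction drag coefficient
IDX_VTH = 11     # torque-constraint speed (m/s)
IDX_CLMAX = 12   # max steady lift coefficient
IDX_L0 = 13      # max lift at full span (N)
IDX_IB = 14      # body roll inertia (kg m^2)
IDX_IWING = 15   # wing inertia about shoulder (kg m^2)
IDX_MB = 16      # body mass (kg)
IDX_MW = 17      # single-wing mass (kg)
IDX_J = 18       # wing mass-moment sum (kg m)
IDX_FRICMODE = 19  # 0 = Blasius (Re-dependent), 1 = fixed reference value
IDX_RHO = 20     # air density (kg m^-3)
IDX_G = 21       # gravitational acceleration (m s^-2)
IDX_MU = 22      # dynamic viscosity of air (Pa s)
PVEC_LEN = 23

# Flight mode codes
MODE_FLAP = 0
MODE_GLIDE = 1

# Engagement outcome codes
OUT_CATCH = 0
OUT_NEAR_MISS = 1
OUT_TIMEOUT = 2
OUT_ERROR = 3

W_B_COEF = 0.098


# ---------------------------------------------------------------------------
# Wing geometry and drag
# ---------------------------------------------------------------------------
@njit(cache=True)
def wing_area(b, p):
    """Wing planform area at span b (linear retraction model)."""
    return p[IDX_SWMAX] * (b - p[IDX_BMIN]) / (p[IDX_BMAX] - p[IDX_BMIN])


@njit(cache=True)
def c_torque(v, v_thresh):
    """Thrust decrement due to the muscle torque limit: min(1, v_thresh/v)."""
    return min(1.0, v_thresh / v)


@njit(cache=True)
def friction_cd(v, b, p):
    """Wing friction drag coefficient.

    Blasius laminar flat-plate solution (both wetted sides) at the Reynolds
    number of the mean chord, or the fixed reference coefficient if the
    morphology is configured that way.  A degenerate wing (zero area at
    b = b_min) returns the reference constant; the zero area annihilates
    the friction term regardless.
    """
    if p[IDX_FRICMODE] == 1.0:
        return p[IDX_CDFRIC]
    s = wing_area(b, p)
    if s <= 0.0:
        return p[IDX_CDFRIC]
    chord = s / b
    re = p[IDX_RHO] * v * chord / p[IDX_MU]
    return 2.0 * 1.328 / math.sqrt(re)


# ---------------------------------------------------------------------------
# Lift limits and thrust-minus-drag
# ---------------------------------------------------------------------------
@njit(cache=True)
def max_lift_gliding(v, p):
    """Maximum achievable gliding lift and the span that achieves it.

    The stall-limited lift grows with span while the muscle-torque-limited
    lift falls with span; their crossing gives the max-lift span b_ml.  When
    the crossing lies beyond full span, lift is capped by the smaller of the
    full-span stall limit and L0.
    Returns (L_max, b_ml).
    """
    b_min = p[IDX_BMIN]
    b_max = p[IDX_BMAX]
    q_full = 0.5 * p[IDX_RHO] * p[IDX_SWMAX] * p[IDX_CLMAX] * v * v
    b_ml = (b_max - b_min) * math.sqrt(p[IDX_L0] / q_full) + b_min
    if b_ml >= b_max:
        return min(p[IDX_L0], q_full), b_max
    l_max = 0.5 * p[IDX_RHO] * wing_area(b_ml, p) * p[IDX_CLMAX] * v * v
    return l_max, b_ml


@njit(cache=True)
def glide_td(L, b, v, p):
    """Net thrust-minus-drag (always <= 0) while gliding at span b, lift L."""
    s = wing_area(b, p)
    rho = p[IDX_RHO]
    qv2 = rho * v * v
    par = (p[IDX_CDBODY] * p[IDX_SB] + friction_cd(v, b, p) * s) * 0.5 * qv2
    if s <= 0.0 or L == 0.0:
        return -par
    cl = 2.0 * L / (s * qv2)
    ar = b * b / s
    induced = cl * cl * s / (2.0 * math.pi * ar) * qv2
    return -par - induced


@njit(cache=True)
def optimal_glide_span(L, v, p):
    """Span that achieves lift L while gliding with the least drag.

    Closed-form optimum balancing induced drag (falls with span) against
    friction drag (grows with span), followed by the truncation cascade:
    clip to [b_min, b_max], clip to the torque bound L0*b_max/L, and if the
    implied lift coefficient exceeds c_l_max recompute the span at c_l_max
    and re-clip.  Assumes L is achievable at v (cap at max_lift_gliding
    first).  Returns the span.
    """
    b_min = p[IDX_BMIN]
    b_max = p[IDX_BMAX]
    if L <= 0.0:
        return b_min
    rho_v2 = p[IDX_RHO] * v * v
    cdf = friction_cd(v, b_max, p)
    b = ((b_max - b_min) * 8.0 * L * L
         / (math.pi * cdf * p[IDX_SWMAX] * rho_v2 * rho_v2)) ** (1.0 / 3.0)
    b_torque = p[IDX_L0] * b_max / L
    b = max(b_min, min(b, b_max, b_torque))
    s = wing_area(b, p)
    cl = 2.0 * L / (s * rho_v2) if s > 0.0 else 2.0 * p[IDX_CLMAX]
    if cl > p[IDX_CLMAX]:
        b = 2.0 * L * (b_max - b_min) / (p[IDX_SWMAX] * p[IDX_CLMAX] * rho_v2) + b_min
        b = max(b_min, min(b, b_max))
    return b


@njit(cache=True)
def flap_wing_msq(p):
    """Area-weighted mean-square flapping speed of the wing,
    0.5 * (pi * f * sin(theta/2) * l_w)^2."""
    u = math.pi * p[IDX_F] * math.sin(0.5 * p[IDX_THETA]) * p[IDX_LW]
    return 0.5 * u * u


@njit(cache=True)
def flap_max_lift(v, p):
    """Maximum flapping lift: the torque limit L0, or the stall limit at
    the flapping-augmented dynamic pressure when that is lower (only the
    case near the minimum flying speed)."""
    q2 = v * v + flap_wing_msq(p)
    return min(p[IDX_L0],
               0.5 * p[IDX_RHO] * p[IDX_SWMAX] * p[IDX_CLMAX] * q2)


@njit(cache=True)
def flap_td(L, v, p):
    """Net thrust-minus-drag while flapping at full span and max frequency.

    Wingbeat-averaged force law: the flapping thrust carries a quadratic
    penalty in the wingbeat-averaged lift coefficient and the muscle torque
    decrement; parasite and induced drag are subtracted.  The lift
    coefficient in the penalty and induced terms is referenced to the
    flapping-augmented dynamic pressure (airspeed plus mean-square wing
    speed), which is indistinguishable from the airspeed reference at
    cruise but keeps the quadratic penalty bounded near stall.
    """
    rho = p[IDX_RHO]
    b = p[IDX_BMAX]
    s = p[IDX_SWMAX]
    q2 = v * v + flap_wing_msq(p)
    cl = 2.0 * L / (s * rho * q2)
    clm = p[IDX_CLMAX]
    thrust = ((1.0 - cl * cl / (clm * clm))
              * math.pi ** 3 / 16.0 * rho * b * b
              * math.sin(0.5 * p[IDX_THETA]) ** 2
              * p[IDX_F] ** 2 * p[IDX_LW] ** 2
              * c_torque(v, p[IDX_VTH]))
    par = (p[IDX_CDBODY] * p[IDX_SB] + friction_cd(v, b, p) * s) \
        * 0.5 * rho * v * v
    induced = cl * cl * s / (2.0 * math.pi * p[IDX_ARMAX]) * rho * q2
    return thrust - par - induced


@njit(cache=True)
def resolve_forces(L_desired, v, p):
    """Choose flapping or gliding to meet the desired lift with max thrust.

    Both modes cap the desired lift at their own maximum (flapping: L0;
    gliding: the torque/stall optimum).  The mode that comes closer to the
    demand wins; on a tie the mode with the larger net thrust wins, and an
    exact tie goes to gliding.  Returns (L, TD, mode, cl, b, saturated).
    """
    qv2 = p[IDX_RHO] * v * v
    # flapping branch
    lf = min(L_desired, flap_max_lift(v, p))
    tdf = flap_td(lf, v, p)
    # gliding branch
    lg_max, _ = max_lift_gliding(v, p)
    lg = min(L_desired, lg_max)
    bg = optimal_glide_span(lg, v, p)
    tdg = glide_td(lg, bg, v, p)
    tol = 1e-12 + 1e-9 * L_desired
    if lf > lg + tol:
        mode = MODE_FLAP
    elif lg > lf + tol:
        mode = MODE_GLIDE
    else:
        mode = MODE_GLIDE if tdg >= tdf else MODE_FLAP
    if mode == MODE_FLAP:
        L, td, b = lf, tdf, p[IDX_BMAX]
        s = p[IDX_SWMAX]
    else:
        L, td, b = lg, tdg, bg
        s = wing_area(b, p)
    cl = 2.0 * L / (s * qv2) if s > 0.0 else 0.0
    saturated = L < L_desired - tol
    return L, td, mode, cl, b, saturated


# ---------------------------------------------------------------------------
# Roll performance
# ---------------------------------------------------------------------------
@njit(cache=True)
def roll_inertia(phi, p):
    """Whole-body roll inertia at retraction fraction phi."""
    wing = (p[IDX_IWING] * phi * phi
            + 0.25 * W_B_COEF ** 2 * p[IDX_MB] ** 0.70 * p[IDX_MW]
            + W_B_COEF * p[IDX_MB] ** 0.35 * p[IDX_J] * phi)
    return p[IDX_IB] + 2.0 * wing


@njit(cache=True)
def max_roll_acceleration(v, p):
    """Maximum roll acceleration, torque and inertia at airspeed v.

    Antisymmetric lift of +/- half the maximum attainable lift on each wing,
    applied at quarter-span, at the span that maximizes lift (which also
    maximizes roll acceleration).  Returns (omega_dot, M, I, b_roll).
    """
    l_max, b_ml = max_lift_gliding(v, p)
    m_roll = l_max * b_ml / 4.0
    inertia = roll_inertia(b_ml / p[IDX_BMAX], p)
    return m_roll / inertia, m_roll, inertia, b_ml


@njit(cache=True)
def bang_bang_sign(gamma, omega, max_accel):
    """Minimum-time roll rule: accelerate toward the target bank angle,
    decelerating once the stopping distance omega^2/(2*max_accel) would
    overshoot the remaining angle gamma."""
    if gamma == 0.0:
        if omega > 0.0:
            return -1.0
        if omega < 0.0:
            return 1.0
        return 0.0
    s = 1.0 if gamma > 0.0 else -1.0
    if omega * gamma > 0.0 and omega * omega > 2.0 * max_accel * abs(gamma):
        return -s
    return s


@njit(cache=True)
def roll_accel_command(gamma, omega, max_accel, dt):
    """Proximate time-optimal roll acceleration.

    Tracks the minimum-time velocity profile omega_des(gamma) =
    sign(gamma) * sqrt(2 * max_accel * |gamma|): far from the target bank
    this reproduces bang-bang switching (accelerate at +max, decelerate at
    -max from the half-way switch point); near the target the profile is
    linear in the remaining angle (settle within ~2 steps), so a settled
    bird holds its bank with near-zero torque instead of chattering in a
    +max/-max limit cycle at the integration frequency."""
    om_des = min(math.sqrt(2.0 * max_accel * abs(gamma)),
                 abs(gamma) / (2.0 * dt))
    if gamma < 0.0:
        om_des = -om_des
    a = (om_des - omega) / dt
    if a > max_accel:
        return max_accel
    if a < -max_accel:
        return -max_accel
    return a


# ---------------------------------------------------------------------------
# Small vector helpers (explicit components: numba-friendly)
# ---------------------------------------------------------------------------
@njit(cache=True)
def _norm3(x, y, z):
    return math.sqrt(x * x + y * y + z * z)


@njit(cache=True)
def zero_bank_axes(vx, vy, vz, prev_ey0x, prev_ey0y, prev_ey0z):
    """Zero-bank body axes from velocity: e_x along v, e_y0 horizontal.

    Falls back to the previous lateral axis when the velocity is vertical
    (the horizontal reference is then undefined).
    Returns (ex, ey0, ez0) as 9 floats.
    """
    vn = _norm3(vx, vy, vz)
    exx, exy, exz = vx / vn, vy / vn, vz / vn
    # e_z_world x e_x
    hx, hy = -exy, exx
    hn = math.sqrt(hx * hx + hy * hy)
    if hn > 1e-9:
        ey0x, ey0y, ey0z = hx / hn, hy / hn, 0.0
    else:
        # orthogonalize the carried lateral axis against the new roll axis
        d = prev_ey0x * exx + prev_ey0y * exy + prev_ey0z * exz
        ey0x = prev_ey0x - d * exx
        ey0y = prev_ey0y - d * exy
        ey0z = prev_ey0z - d * exz
        n = _norm3(ey0x, ey0y, ey0z)
        ey0x, ey0y, ey0z = ey0x / n, ey0y / n, ey0z / n
    # e_z0 = e_x cross e_y0
    ez0x = exy * ey0z - exz * ey0y
    ez0y = exz * ey0x - exx * ey0z
    ez0z = exx * ey0y - exy * ey0x
    return exx, exy, exz, ey0x, ey0y, ey0z, ez0x, ez0y, ez0z


@njit(cache=True)
def banked_axes(omega_roll, ey0x, ey0y, ey0z, ez0x, ez0y, ez0z):
    """Rotate the zero-bank lateral/yaw axes by the roll angle about e_x."""
    c = math.cos(omega_roll)
    s = math.sin(omega_roll)
    eyx = c * ey0x + s * ez0x
    eyy = c * ey0y + s * ez0y
    eyz = c * ey0z + s * ez0z
    ezx = -s * ey0x + c * ez0x
    ezy = -s * ey0y + c * ez0y
    ezz = -s * ey0z + c * ez0z
    return eyx, eyy, eyz, ezx, ezy, ezz


# ---------------------------------------------------------------------------
# One bird control + integration step
# ---------------------------------------------------------------------------
@njit(cache=True)
def control_step(state, p, ax_cmd, ay_cmd, az_cmd, dt, chi, u_chi,
                 lf_cap, roll_cap, strict_sign):
    """Advance one bird by dt under a commanded acceleration.

    ``state`` is a float64 array:
      [0:3] r, [3:6] v, [6:9] previous a, [9] roll angle, [10] roll rate,
      [11:14] carried zero-bank lateral axis, [14] previous c_l,
      [15] first-step flag (1.0 until the first force evaluation).
    ``lf_cap``/``roll_cap`` cap the load factor and roll acceleration
    (np.inf disables).  Returns (L, TD, mode, omega_dot, load_factor).
    """
    g = p[IDX_G]
    m = p[IDX_M]
    vx, vy, vz = state[3], state[4], state[5]
    v = _norm3(vx, vy, vz)

    exx, exy, exz, ey0x, ey0y, ey0z, ez0x, ez0y, ez0z = zero_bank_axes(
        vx, vy, vz, state[11], state[12], state[13])
    state[11], state[12], state[13] = ey0x, ey0y, ey0z
    om_angle = state[9]
    eyx, eyy, eyz, ezx, ezy, ezz = banked_axes(
        om_angle, ey0x, ey0y, ey0z, ez0x, ez0y, ez0z)

    # weight support: compensate gravity, project on the body y'-z' plane
    gz = -g if strict_sign else g
    asx, asy, asz = ax_cmd, ay_cmd, az_cmd + gz
    py = asx * eyx + asy * eyy + asz * eyz
    pz = asx * ezx + asy * ezy + asz * ezz
    a_proj = math.sqrt(py * py + pz * pz)

    # roll control: bang-bang toward the bank angle that aligns e_z' with
    # the projected demand
    if a_proj > 1e-12:
        gamma = math.atan2(-py, pz)
    else:
        gamma = 0.0
    om_dot_max, _, _, _ = max_roll_acceleration(v, p)
    if om_dot_max > roll_cap:
        om_dot_max = roll_cap
    om_dot = roll_accel_command(gamma, state[10], om_dot_max, dt)
    state[9] = state[9] + state[10] * dt
    state[10] = state[10] + om_dot * dt

    # lift control: flap or glide to meet L* with max forward thrust
    l_star = m * a_proj
    if l_star > lf_cap * m * g:
        l_star = lf_cap * m * g
    L, td, mode, cl, b, sat = resolve_forces(l_star, v, p)
    if chi > 0.0:
        dcl = abs(cl - state[14]) / dt
        L = L * (1.0 + chi * dcl * u_chi)
        if L < 0.0:
            L = 0.0
    state[14] = cl

    # total force and velocity-Verlet update
    fx = td * exx + L * ezx
    fy = td * exy + L * ezy
    fz = td * exz + L * ezz - m * g
    anx, any_, anz = fx / m, fy / m, fz / m
    if state[15] == 1.0:
        state[6], state[7], state[8] = anx, any_, anz
        state[15] = 0.0
    aox, aoy, aoz = state[6], state[7], state[8]
    state[0] += vx * dt + 0.5 * anx * dt * dt
    state[1] += vy * dt + 0.5 * any_ * dt * dt
    state[2] += vz * dt + 0.5 * anz * dt * dt
    state[3] += 0.5 * (aox + anx) * dt
    state[4] += 0.5 * (aoy + any_) * dt
    state[5] += 0.5 * (aoz + anz) * dt
    state[6], state[7], state[8] = anx, any_, anz
    return L, td, mode, om_dot, L / (m * g)


@njit(cache=True)
def init_bird_state(rx, ry, rz, vx, vy, vz):
    s = np.zeros(16, dtype=np.float64)
    s[0], s[1], s[2] = rx, ry, rz
    s[3], s[4], s[5] = vx, vy, vz
    # default carried lateral axis: horizontal, orthogonal to v if possible
    s[11], s[12], s[13] = 0.0, 1.0, 0.0
    s[15] = 1.0
    return s


# ---------------------------------------------------------------------------
# Prey forcing functions
# ---------------------------------------------------------------------------
@njit(cache=True)
def prey_amax(v, p):
    """Attainable normal acceleration at airspeed v (flap or glide).

    Self-limiting: it falls with airspeed, so a maneuvering bird that
    slows down is commanded smaller accelerations in future steps."""
    lg, _ = max_lift_gliding(v, p)
    l_max = max(lg, flap_max_lift(v, p))
    return l_max / p[IDX_M]


@njit(cache=True)
def straight_forcing(state, p, dx, dy, dz):
    """Accelerate toward a fixed heading, capped so the combination with
    gravity stays within the attainable normal acceleration."""
    g = p[IDX_G]
    vx, vy, vz = state[3], state[4], state[5]
    vn = _norm3(vx, vy, vz)
    ux, uy, uz = vx / vn, vy / vn, vz / vn
    # component of the target direction perpendicular to the velocity
    d = dx * ux + dy * uy + dz * uz
    px, py, pz = dx - d * ux, dy - d * uy, dz - d * uz
    pn = _norm3(px, py, pz)
    amax = prey_amax(vn, p)
    cap = math.sqrt(max(amax * amax - g * g, 0.0))
    if pn < 1e-9:
        return 0.0, 0.0, 0.0
    mag = min(cap, cap * pn)  # taper as alignment completes
    return mag * px / pn, mag * py / pn, mag * pz / pn


@njit(cache=True)
def smooth_forcing(t, state, p, c1, c2, c3, c4, kappa):
    """Harmonically modulated centripetal demand plus altitude restoration.

    The lateral magnitude is (c1 sin(c2 t) + c1) * c3 * a_max along the
    horizontal unit vector perpendicular to the velocity.
    """
    vx, vy, vz = state[3], state[4], state[5]
    vn = _norm3(vx, vy, vz)
    # h = e_x' x e_z, horizontal and perpendicular to velocity
    hx, hy = vy / vn, -vx / vn
    hn = math.sqrt(hx * hx + hy * hy)
    if hn < 1e-9:
        return 0.0, 0.0, -c4 * kappa
    hx, hy = hx / hn, hy / hn
    amax = prey_amax(vn, p)
    mag = (c1 * math.sin(c2 * t) + c1) * c3 * amax
    return mag * hx, mag * hy, -c4 * kappa


@njit(cache=True)
def nonsmooth_forcing(state, p, q, c5, c6, c7, c8, c9_rad, kappa):
    """Stepwise random-direction demand: with probability c5 per step the
    direction blends toward a fresh random near-horizontal unit vector.
    Callers scale c5 with dt so the switching *rate* is step-invariant."""
    if np.random.random() < c5:
        az = np.random.uniform(0.0, 2.0 * math.pi)
        el = np.random.uniform(-c9_rad, c9_rad)
        qx = math.cos(el) * math.cos(az)
        qy = math.cos(el) * math.sin(az)
        qz = math.sin(el)
        nx = c8 * q[0] + (1.0 - c8) * qx
        ny = c8 * q[1] + (1.0 - c8) * qy
        nz = c8 * q[2] + (1.0 - c8) * qz
        n = _norm3(nx, ny, nz)
        q[0], q[1], q[2] = nx / n, ny / n, nz / n
    vn = _norm3(state[3], state[4], state[5])
    amax = prey_amax(vn, p)
    return q[0] * c6 * amax, q[1] * c6 * amax, q[2] * c6 * amax - c7 * kappa


@njit(cache=True)
def random_unit_sphere():
    az = np.random.uniform(0.0, 2.0 * math.pi)
    cz = np.random.uniform(-1.0, 1.0)
    sz = math.sqrt(1.0 - cz * cz)
    return sz * math.cos(az), sz * math.sin(az), cz


@njit(cache=True)
def draw_q(c9_rad):
    az = np.random.uniform(0.0, 2.0 * math.pi)
    el = np.random.uniform(-c9_rad, c9_rad)
    return (math.cos(el) * math.cos(az),
            math.cos(el) * math.sin(az),
            math.sin(el))


# ---------------------------------------------------------------------------
# Vision
# ---------------------------------------------------------------------------
@njit(cache=True)
def measure_los(rdx, rdy, rdz, xi):
    """Noisy line-of-sight: angular error of magnitude U(0, xi), direction
    uniform on the circle perpendicular to the true line of sight, scaled
    by range."""
    rn = _norm3(rdx, rdy, rdz)
    if xi <= 0.0:
        return rdx, rdy, rdz
    ux, uy, uz = rdx / rn, rdy / rn, rdz / rn
    # orthonormal pair perpendicular to u
    if abs(ux) < 0.9:
        ax, ay, az = 1.0, 0.0, 0.0
    else:
        ax, ay, az = 0.0, 1.0, 0.0
    e1x = uy * az - uz * ay
    e1y = uz * ax - ux * az
    e1z = ux * ay - uy * ax
    n1 = _norm3(e1x, e1y, e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    mag = np.random.uniform(0.0, xi)
    ang = np.random.uniform(0.0, 2.0 * math.pi)
    ex = mag * (math.cos(ang) * e1x + math.sin(ang) * e2x)
    ey = mag * (math.cos(ang) * e1y + math.sin(ang) * e2y)
    ez = mag * (math.cos(ang) * e1z + math.sin(ang) * e2z)
    return rdx + ex * rn, rdy + ey * rn, rdz + ez * rn


@njit(cache=True)
def los_rate(rx, ry, rz, rpx, rpy, rpz, dt_sample):
    """Line-of-sight angular rate from two range-vector measurements:
    lambda_dot = r x v_rel / |r|^2 with finite-difference v_rel."""
    vdx = (rx - rpx) / dt_sample
    vdy = (ry - rpy) / dt_sample
    vdz = (rz - rpz) / dt_sample
    r2 = rx * rx + ry * ry + rz * rz
    lx = (ry * vdz - rz * vdy) / r2
    ly = (rz * vdx - rx * vdz) / r2
    lz = (rx * vdy - ry * vdx) / r2
    return lx, ly, lz


# ---------------------------------------------------------------------------
# Full engagement
# ---------------------------------------------------------------------------
@njit(cache=True)
def run_engagement(pf, pp, nav_n, altitude, horiz_dist, tau, xi, chi,
                   prey_mode, dt, timeout, catch_r, miss_r, cone_cos,
                   v0_prey, v0_falcon, seed, c_params,
                   lf_cap, roll_cap, strict_sign,
                   log_every, log_out):
    """Simulate one falcon-vs-prey encounter.

    prey_mode: 0 straight, 1 smooth, 2 non-smooth.
    c_params: array [c1..c9] with c9 in degrees.
    log_out: float64 (n_log, 12) buffer filled every ``log_every`` steps with
    (t, rf, rp, |vf|, |vp|, roll angle, load factor) when log_every > 0.
    Returns (outcome, t_end, intercept_speed, min_dist, n_steps, n_logged).
    """
    np.random.seed(seed)
    g = pf[IDX_G]

    # prey at the origin, random orientation, given initial speed
    dx, dy, dz = random_unit_sphere()
    prey = init_bird_state(0.0, 0.0, 0.0, v0_prey * dx, v0_prey * dy,
                           v0_prey * dz)
    # straight-mode target heading: uniform azimuth, elevation within 2.5 deg
    t_az = np.random.uniform(0.0, 2.0 * math.pi)
    t_el = np.random.uniform(-2.5, 2.5) * math.pi / 180.0
    tgt_x = math.cos(t_el) * math.cos(t_az)
    tgt_y = math.cos(t_el) * math.sin(t_az)
    tgt_z = math.sin(t_el)
    c9_rad = c_params[8] * math.pi / 180.0
    c5_eff = min(1.0, c_params[4] * dt / 1.0e-4)  # rate-invariant switching
    q = np.empty(3, dtype=np.float64)
    q[0], q[1], q[2] = draw_q(c9_rad)

    # falcon offset horizontally and vertically, flying straight at the prey
    fx, fy, fz = horiz_dist, 0.0, altitude
    rn = _norm3(fx, fy, fz)
    if rn < 1e-9:
        return OUT_CATCH, 0.0, v0_falcon, 0.0, 0, 0
    falcon = init_bird_state(fx, fy, fz, -v0_falcon * fx / rn,
                             -v0_falcon * fy / rn, -v0_falcon * fz / rn)

    # vision sample-and-hold state
    lamx, lamy, lamz = 0.0, 0.0, 0.0
    have_prev = False
    have_rate = False
    rhx, rhy, rhz = 0.0, 0.0, 0.0
    t_last_sample = 0.0
    sample_interval = max(tau, dt)

    n_steps = int(round(timeout / dt))
    min_dist = 1e30
    armed = False
    outcome = OUT_TIMEOUT
    t = 0.0
    t_end = timeout
    speed_end = 0.0
    n_logged = 0

    for step in range(n_steps + 1):
        t = step * dt
        ddx = prey[0] - falcon[0]
        ddy = prey[1] - falcon[1]
        ddz = prey[2] - falcon[2]
        dist = _norm3(ddx, ddy, ddz)
        if not math.isfinite(dist):
            outcome = OUT_ERROR
            t_end = t
            break
        if dist < min_dist:
            min_dist = dist
        vfn = _norm3(falcon[3], falcon[4], falcon[5])
        if log_every > 0 and step % log_every == 0 and n_logged < log_out.shape[0]:
            log_out[n_logged, 0] = t
            log_out[n_logged, 1] = falcon[0]
            log_out[n_logged, 2] = falcon[1]
            log_out[n_logged, 3] = falcon[2]
            log_out[n_logged, 4] = prey[0]
            log_out[n_logged, 5] = prey[1]
            log_out[n_logged, 6] = prey[2]
            log_out[n_logged, 7] = vfn
            log_out[n_logged, 8] = _norm3(prey[3], prey[4], prey[5])
            log_out[n_logged, 9] = falcon[9]
            log_out[n_logged, 10] = dist
            log_out[n_logged, 11] = 0.0
            n_logged += 1
        if dist <= catch_r:
            outcome = OUT_CATCH
            t_end = t
            speed_end = vfn
            break
        if armed and dist > miss_r:
            # prey lost into the rear blind cone -> unrecoverable near-miss
            exfx, exfy, exfz = (falcon[3] / vfn, falcon[4] / vfn,
                                falcon[5] / vfn)
            behind = -(ddx * exfx + ddy * exfy + ddz * exfz) / dist
            if behind >= cone_cos:
                outcome = OUT_NEAR_MISS
                t_end = t
                speed_end = vfn
                break
        if dist < miss_r:
            armed = True
        if step == n_steps:
            outcome = OUT_TIMEOUT
            t_end = t
            speed_end = vfn
            break

        # ---- prey forcing and step ----
        kappa = prey[2]  # altitude offset from its starting altitude (0)
        if prey_mode == 0:
            pax, pay, paz = straight_forcing(prey, pp, tgt_x, tgt_y, tgt_z)
        elif prey_mode == 1:
            pax, pay, paz = smooth_forcing(t, prey, pp, c_params[0],
                                           c_params[1], c_params[2],
                                           c_params[3], kappa)
        else:
            pax, pay, paz = nonsmooth_forcing(prey, pp, q, c5_eff,
                                              c_params[5], c_params[6],
                                              c_params[7], c9_rad, kappa)
        control_step(prey, pp, pax, pay, paz, dt, 0.0, 0.0,
                     np.inf, np.inf, False)

        # ---- falcon vision (sampled), guidance, control ----
        if t == 0.0 or t - t_last_sample >= sample_interval - 0.5 * dt:
            mx, my, mz = measure_los(ddx, ddy, ddz, xi)
            if have_prev:
                lamx, lamy, lamz = los_rate(mx, my, mz, rhx, rhy, rhz,
                                            t - t_last_sample)
                have_rate = True
            rhx, rhy, rhz = mx, my, mz
            have_prev = True
            t_last_sample = t
        if have_rate:
            fax = nav_n * (lamy * falcon[5] - lamz * falcon[4])
            fay = nav_n * (lamz * falcon[3] - lamx * falcon[5])
            faz = nav_n * (lamx * falcon[4] - lamy * falcon[3])
        else:
            fax, fay, faz = 0.0, 0.0, 0.0
        u_chi = np.random.uniform(-1.0, 1.0) if chi > 0.0 else 0.0
        control_step(falcon, pf, fax, fay, faz, dt, chi, u_chi,
                     lf_cap, roll_cap, strict_sign)

        if _norm3(falcon[3], falcon[4], falcon[5]) < 1e-6 or \
           _norm3(prey[3], prey[4], prey[5]) < 1e-6:
            outcome = OUT_ERROR
            t_end = t
            break

    return outcome, t_end, speed_end, min_dist, int(round(t / dt)), n_logged


@njit(cache=True)
def run_prey_free(pp, prey_mode, duration, dt, seed, c_params, v0,
                  log_every, log_out):
    """Prey flying alone under its forcing function; used to verify the
    forcing statistics (load factor, roll acceleration, altitude band,
    isotropy).

    log_out: (n_log, 8) buffer: t, z, load factor, |omega_dot|, command x,
    command y, speed, roll rate.  Returns number of rows written.
    """
    np.random.seed(seed)
    dx, dy, dz = random_unit_sphere()
    prey = init_bird_state(0.0, 0.0, 0.0, v0 * dx, v0 * dy, v0 * dz)
    t_az = np.random.uniform(0.0, 2.0 * math.pi)
    t_el = np.random.uniform(-2.5, 2.5) * math.pi / 180.0
    tgt = (math.cos(t_el) * math.cos(t_az),
           math.cos(t_el) * math.sin(t_az),
           math.sin(t_el))
    c9_rad = c_params[8] * math.pi / 180.0
    c5_eff = min(1.0, c_params[4] * dt / 1.0e-4)
    q = np.empty(3, dtype=np.float64)
    q[0], q[1], q[2] = draw_q(c9_rad)

    n_steps = int(round(duration / dt))
    n_logged = 0
    for step in range(n_steps):
        t = step * dt
        kappa = prey[2]
        if prey_mode == 0:
            ax, ay, az = straight_forcing(prey, pp, tgt[0], tgt[1], tgt[2])
        elif prey_mode == 1:
            ax, ay, az = smooth_forcing(t, prey, pp, c_params[0], c_params[1],
                                        c_params[2], c_params[3], kappa)
        else:
            ax, ay, az = nonsmooth_forcing(prey, pp, q, c5_eff,
                                           c_params[5], c_params[6],
                                           c_params[7], c9_rad, kappa)
        L, td, mode, om_dot, lf = control_step(prey, pp, ax, ay, az, dt,
                                               0.0, 0.0, np.inf, np.inf,
                                               False)
        if log_every > 0 and step % log_every == 0 and \
                n_logged < log_out.shape[0]:
            log_out[n_logged, 0] = t
            log_out[n_logged, 1] = prey[2]
            log_out[n_logged, 2] = lf
            log_out[n_logged, 3] = abs(om_dot)
            log_out[n_logged, 4] = ax
            log_out[n_logged, 5] = ay
            log_out[n_logged, 6] = _norm3(prey[3], prey[4], prey[5])
            log_out[n_logged, 7] = prey[10]
            n_logged += 1
    return n_logged
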