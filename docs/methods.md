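# Model and methods

`stoopsim` simulates three-dimensional aerial pursuit between a model
peregrine falcon and a model starling. Both birds are point masses with a
roll degree of freedom, flown by the same wingbeat-averaged aerodynamic
force law; they differ only in their measured morphology. The falcon is
guided by pure proportional navigation (PPN) fed by noisy, sampled vision;
the starling follows an open-loop forcing function (straight, smoothly
turning, or jinking). The package's purpose is to map catch success over
attack strategies — the navigation gain N and the initial altitude and
horizontal distance of the attack — by Monte-Carlo simulation and
logistic GAM smoothing.

## Aerodynamics

Forces are averaged over the wingbeat and resolved into lift L along the
body yaw axis and net thrust-minus-drag TD along the velocity:

* **Flapping** (full span b_max, maximum wingbeat frequency f):

      TD = (1 − c_l²/c_l,max²) · (π³/16) ρ b² sin²(θ/2) f² l_w² · c_torque
           − (c_d,body S_b + c_d,fric S_w) · ½ρv² − c_l² S_w ρ v² / (2π AR)

  with `c_torque = min(1, v_thresh/v)` the muscle-torque decrement.
  Flapping lift is capped at L0 = 1.7 m g (torque limit at full span).
* **Gliding** (f = 0): no thrust; the span b is retracted to minimize
  drag at the demanded lift. Wing area varies linearly with span,
  S_w = S_w,max (b − b_min)/(b_max − b_min), and AR = b²/S_w. The
  drag-minimizing span has the closed form
  b* = [(b_max − b_min) · 8L² / (π c_d,fric S_w,max (ρv²)²)]^{1/3},
  truncated to [b_min, b_max], to the torque bound L0·b_max/L, and to the
  stall boundary (c_l ≤ c_l,max).
* **Gliding lift limit**: the stall-limited lift grows with span while
  the torque-limited lift falls with it; the crossing defines the
  max-lift span b_ml and L_max(v) ∝ v at high speed, which is what makes
  fast flight the falcon's route to high load factors.
* **Roll**: antisymmetric lift of ±L_max/2 per wing acting at quarter
  span gives the roll torque; the whole-body roll inertia combines the
  measured body and wing inertias through the retraction fraction
  φ = b/b_max. The span that maximizes lift also maximizes roll
  acceleration, so the roll controller always uses b_ml.

Two numerical regularizations depart deliberately from the idealized
formulas:

1. The wingbeat-averaged lift coefficient in the flapping penalty and
   induced-drag terms is referenced to the flapping-augmented dynamic
   pressure v² + ⟨U_w²⟩, where ⟨U_w²⟩ = ½(πf sin(θ/2) l_w)² is the
   area-weighted mean-square wing speed (the same quantity that appears
   in the thrust derivation). At cruise this is indistinguishable from
   the airspeed reference (< 0.5% at 29 m/s); near stall it keeps the
   quadratic penalty bounded, where the raw form diverges as v → 0 and
   destabilizes the integration.
2. The friction drag coefficient follows the Blasius laminar flat-plate
   solution, c_d,fric = 2·1.328/√Re with Re built on the mean chord
   S_w/b (a fixed tabulated coefficient is available as a config switch).
   Inside the span-optimization closed form the coefficient is evaluated
   at full span, since the closed form assumes it constant.

Parasite drag uses ½ρv²; only that convention reproduces the model's
terminal dive speeds.

## Guidance, vision, and control

The falcon measures the line of sight r_d every τ (default 50 ms) with an
angular error of magnitude U(0, ξ) and direction uniform on the circle
around the true line of sight, scaled by range. Two successive
measurements give a finite-difference line-of-sight rate
λ̇ = r̂ × v̂ / |r̂|², held between samples; the command is a* = N λ̇ × v,
perpendicular to the velocity by construction. Before two sightings exist
the command is zero.

The error bound ξ (default 0.007 rad) derives from a retinal *rate*
threshold of about 8°/s integrated over the differencing window, so by
default the per-measurement bound scales with the sampling interval
(0.007 rad per 50 ms ≡ 0.14 rad/s). This matters when τ is varied:
with a fixed per-measurement bound, differencing over a 0.1 ms window
would amplify the noise 500-fold and no interception could succeed,
contrary to the behavior the model is meant to capture. A
`vision_noise="fixed"` switch preserves the τ-independent interpretation.

Control splits the commanded acceleration into (i) a lift demand
L* = m|a_proj|, where a_proj is the command plus gravity compensation
projected on the body (e_y, e_z) plane, and (ii) a bank-angle target.
Lift is met by whichever of flapping or gliding comes closer to L* (ties
broken by larger TD, then gliding); if neither reaches it the maximum
attainable lift is applied. Bank is tracked by a proximate time-optimal
servo: far from the target it follows the minimum-time bang-bang profile
ω_des = sign(γ)√(2ω̇_max|γ|), switching at half the angle exactly as the
analytic bang-bang rule; within the last-step neighborhood a linear
segment settles the bank without the ±ω̇_max limit cycle that raw
bang-bang exhibits at discrete time steps. The control-error parameter χ
(default 0) perturbs achieved lift multiplicatively in proportion to
|dc_l/dt|.

Body axes are recomputed from the velocity each step (perfect pitch/yaw
stability), then banked by the carried roll angle; when the velocity is
vertical the lateral reference falls back to its previous value.
Orthonormality is therefore exact by construction.

## Integration

Translation uses velocity Verlet with one force evaluation per step
(the velocity update trapezoids the previous and current accelerations),
exact for constant gravity; roll uses explicit Euler. The default step is
dt = 10⁻⁴ s. Monte-Carlo sweeps run at dt = 10⁻³ s for speed; the
convergence report (mean per-step discrepancy between runs at dt and
dt/10 with identical seeding) shows roughly an order of magnitude
improvement per decade, and catch fractions at the reference stoop cell
agree within a few points between the two steps. The jink-switching
probability c₅ is quoted per 10⁻⁴ s reference step and is rescaled with
dt so the switching *rate* (80 s⁻¹) is step-invariant.

## Engagements and experiments

The prey starts at the origin at 11 m/s in a uniformly random direction;
the falcon starts at (horizontal distance, altitude) flying straight at
the prey at 16 m/s, lateral axis horizontal. Termination: catch within
0.2 m; near-miss failure when the falcon, having been within 5 m, finds
the prey beyond 5 m inside the 45° blind cone behind it; timeout at 40 s.
Strategy sweeps draw N ∈ [1, 20], altitude ∈ [−200, 1500] m, and
horizontal distance ∈ [0, 800] m uniformly; catch probability is smoothed
with a logistic GAM (penalized additive cubic B-splines, df = 8 per
covariate) and optima are read off a 50³ grid. Each engagement receives
its own integer seed; a run is bit-reproducible given (config, seed).

## What the prey generator does and does not emulate

The forcing functions reproduce the *structure* of the three prey
behaviors: fixed-heading flight with elevation within ±2.5°, harmonic
lateral demand with an altitude-restoring term, and stepwise random
redirection at 80 s⁻¹ with near-horizontal draws. They are not evasive —
the prey never reacts to the falcon.

Under this force law the maneuvering prey saturates its gliding lift
limit, and gliding provides no thrust, so its airspeed equilibrates near
7 m/s (jinking) and 22 m/s (smooth) rather than at the speeds that would
support the literature's reported maneuvering statistics: the measured
long-run mean load factor is ≈ 1.2–1.35 and the mean roll-acceleration
magnitude ≈ 1600 rad/s² (jinking) and ≈ 9 rad/s² (smooth). Sustaining a
mean load factor of ~3.4 within a ±20 m altitude band is not energetically
possible here: lift above 1.7 m g requires gliding, and the implied sink
rate (~4.6 m/s) would breach the band within seconds. The smooth and
straight modes hold their altitude band; the jinking mode holds a looser
(~±100 m, mean-reverting) band for the same reason.

This matters for the strategy surface. A prey with ~0.9 g of sustained
lateral maneuver is far less demanding than one with ~2–3 g: classical
proportional navigation then succeeds from almost any geometry at low N,
and the fitted optimum lands near N ≈ 1, low altitude, with ≈ 95% catch
success, instead of an interior optimum near N ≈ 3 at high altitude.
The qualitative robustness trends survive: catch success falls steeply
for N ≳ 3 at baseline delay, a shorter response delay never hurts, and
τ = 0.1 ms makes low-altitude attacks essentially always succeed.

## Known limitations

* The wingbeat-averaged law is an asymptotic (fast-airspeed) reduction of
  a blade-element model; its envelope speeds carry systematic error at
  both ends (level top speeds come out ~8–10% fast, minimum sustained
  speeds ~15–25% fast; terminal dive speeds are accurate).
* The torque span-bound (arm ∝ b) and the max-lift span formula (arm ∝
  b − b_min) embody two different moment-arm conventions; at combined
  high lift and speed they conflict and the retraction cascade rides the
  stall boundary rather than the drag optimum. Both are kept as printed;
  the optimality oracle applies in the conflict-free regime.
* No pitch/yaw dynamics, no tail model, no wind, no unsteady
  aerodynamics, no contact mechanics at intercept; single prey only.
* Catch outcomes near the optimum ride a knife-edge miss-distance
  distribution (most failed passes miss by 0.2–0.5 m), so catch
  fractions are sensitive to sensing-noise details at the few-points
  level.
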