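# stoopsim

Physics-based simulation of peregrine falcon (*Falco peregrinus*) attacks
on starling-like aerial prey, for studying why falcons stoop: whether,
when, and how much a high-altitude, high-speed dive improves catch
success against prey that fly straight, turn smoothly, or jink
erratically.

Both birds fly under the same quasi-steady, wingbeat-averaged force
model, parametrized by measured morphology (span, wing area, masses,
inertias, drag coefficients). Flapping delivers thrust

TD = (1 − c_l²/c_l,max²) (π³/16) ρ b² sin²(θ/2) f² l_w² · min(1, v_thresh/v) − drag,

while gliding trades wing retraction against induced drag with a
closed-form optimal span. The falcon steers by pure proportional
navigation, **a\* = N λ̇ × v**, where λ̇ is the line-of-sight rate
estimated from noisy position sightings sampled every τ = 50 ms with an
angular error bounded by ξ = 0.007 rad, and N is the navigation
constant. Demands are met by bank-to-turn control: a minimum-time
(bang-bang) roll to the commanded bank, and a flap-or-glide lift
decision that maximizes forward acceleration subject to meeting the
commanded normal acceleration as closely as possible. The model prey is
driven by open-loop forcing functions and is not evasive. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```python
from stoopsim import EngagementConfig, run
from stoopsim import aerodynamics as aero
from stoopsim.morphology import FALCON, STARLING

# flight performance envelopes
print(aero.max_level_speed(FALCON))      # 31.29  m/s level top speed
print(aero.terminal_dive_speed(FALCON))  # 125.87 m/s vertical-dive terminal
print(aero.terminal_dive_speed(STARLING))  # 49.59 m/s

# one stoop from 1500 m altitude and 641 m horizontal offset
# against jinking prey, navigation constant N = 2.8
cfg = EngagementConfig(N=2.8, altitude=1500, horiz_dist=641,
                       prey_mode="nonsmooth", seed=1)
res = run(cfg)
print(res.outcome, round(res.t_end, 2), round(res.intercept_speed, 1))
# catch 21.3 106.5
```

The falcon converts 1500 m of altitude into a ~107 m/s intercept speed
and takes the prey 21.3 s into the attack. Failed passes typically miss
by only 0.2–0.5 m and end as unrecoverable near-misses once the prey
falls into the blind cone behind the attacker.

Batch experiments live in `stoopsim.experiments`: `sweep` runs
Monte-Carlo engagements over uniformly drawn attack strategies
(N ∈ [1, 20], altitude ∈ [−200, 1500] m, horizontal distance
∈ [0, 800] m), `fit_surface` smooths catch success with a logistic GAM
and locates optima, and `robustness_sweep`, `capped_performance_experiment`
and `convergence_report` cover the delay/error, performance-cap, and
integration-step analyses. The same operations are exposed on the
command line:

```bash
stoopsim envelope --species falcon --out envelope.csv
stoopsim run-engagement --seed 3 --out out/
stoopsim sweep --n 2000 --prey-mode nonsmooth --dt 0.001 --out sweep.csv
stoopsim fit-surface --samples sweep.csv
stoopsim convergence --seed 5
```

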