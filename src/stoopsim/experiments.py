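"""Monte-Carlo attack-strategy experiments and response-surface analysis.

Sweeps sample attack strategies (navigation constant N, initial altitude,
initial horizontal distance) uniformly, run independent engagements, and
fit a logistic generalized additive model (GAM) of catch success over the
three strategy coordinates to locate optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from . import engagement as eng
from .engagement import EngagementConfig
from .morphology import BirdMorphology, PhysicalConstants, FALCON, STARLING

__all__ = ["StrategyBounds", "ResponseSurface", "sweep", "fit_surface",
           "robustness_sweep", "capped_performance_experiment",
           "convergence_report"]


@dataclass(frozen=True)
class StrategyBounds:
    """Uniform sampling ranges for attack strategies."""

    N: tuple[float, float] = (1.0, 20.0)
    altitude: tuple[float, float] = (-200.0, 1500.0)
    horiz_dist: tuple[float, float] = (0.0, 800.0)


@dataclass
class ResponseSurface:
    """Fitted smooth of catch probability over (N, altitude, horiz_dist)."""

    result: object
    smoother: BSplines
    samples: pd.DataFrame
    flat: bool = False
    optimum: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.flat:
            return np.full(len(X), float(self.samples["caught"].mean()))
        X = np.asarray(X)
        return np.clip(self.result.predict(exog=np.ones((len(X), 1)),
                                           exog_smooth=X), 0.0, 1.0)

    def locate_optimum(self, bounds: StrategyBounds = StrategyBounds(),
                       n_grid: int = 50) -> dict:
        """Global optimum of the fitted surface on an n_grid^3 lattice."""
        if self.flat:
            self.optimum = None
            return {}
        # stay inside the sampled range: the spline basis is undefined
        # beyond the outermost knots
        s = self.samples

        def rng(col, lo, hi):
            return max(lo, float(s[col].min())), min(hi, float(s[col].max()))

        gn = np.linspace(*rng("N", *bounds.N), n_grid)
        ga = np.linspace(*rng("altitude", *bounds.altitude), n_grid)
        gh = np.linspace(*rng("horiz_dist", *bounds.horiz_dist), n_grid)
        NN, AA, HH = np.meshgrid(gn, ga, gh, indexing="ij")
        X = np.column_stack([NN.ravel(), AA.ravel(), HH.ravel()])
        p = self.predict(X)
        i = int(np.argmax(p))
        self.optimum = {"N": float(X[i, 0]), "altitude": float(X[i, 1]),
                        "horiz_dist": float(X[i, 2]),
                        "p_catch": float(p[i])}
        return self.optimum


def sweep(config: EngagementConfig, n_samples: int, seed: int,
          bounds: StrategyBounds = StrategyBounds(),
          falcon: BirdMorphology = FALCON,
          prey_morph: BirdMorphology = STARLING,
          consts: PhysicalConstants | None = None) -> pd.DataFrame:
    """Monte-Carlo sweep of uniformly drawn attack strategies.

    Returns one row per engagement with the drawn strategy, the outcome,
    and the per-engagement seed (for replay)."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    draws_n = rng.uniform(*bounds.N, n_samples)
    draws_a = rng.uniform(*bounds.altitude, n_samples)
    draws_h = rng.uniform(*bounds.horiz_dist, n_samples)
    eng_seeds = rng.integers(0, 2**31 - 1, n_samples)
    rows = []
    for i in range(n_samples):
        cfg = config.replace(N=float(draws_n[i]), altitude=float(draws_a[i]),
                             horiz_dist=float(draws_h[i]),
                             seed=int(eng_seeds[i]))
        res = eng.run(cfg, falcon=falcon, prey_morph=prey_morph,
                      consts=consts)
        rows.append({"N": cfg.N, "altitude": cfg.altitude,
                     "horiz_dist": cfg.horiz_dist, "outcome": res.outcome,
                     "caught": res.caught, "t_end": res.t_end,
                     "intercept_speed": res.intercept_speed,
                     "min_distance": res.min_distance, "seed": cfg.seed})
    return pd.DataFrame(rows)


def fit_surface(samples: pd.DataFrame, df: int = 8,
                alpha: float = 1.0) -> ResponseSurface:
    """Logistic GAM of catch success with additive penalized B-spline
    smooths of N, altitude, and horizontal distance."""
    y = samples["caught"].to_numpy(dtype=float)
    if y.min() == y.max():  # degenerate: all caught or none
        return ResponseSurface(result=None, smoother=None, samples=samples,
                               flat=True)
    X = samples[["N", "altitude", "horiz_dist"]].to_numpy(dtype=float)
    bs = BSplines(X, df=[df] * 3, degree=[3] * 3)
    model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs,
                   alpha=[alpha] * 3, family=sm.families.Binomial())
    res = model.fit()
    return ResponseSurface(result=res, smoother=bs, samples=samples)


def robustness_sweep(parameter: str, values, config: EngagementConfig,
                     n_samples: int, seed: int,
                     bounds: StrategyBounds = StrategyBounds(),
                     **kwargs) -> dict:
    """Repeat sweep + surface fit for each value of tau, xi, or chi;
    reports the optimum drift."""
    if parameter not in ("tau", "xi", "chi"):
        raise ValueError("parameter must be tau, xi, or chi")
    out = {}
    for j, val in enumerate(values):
        cfg = config.replace(**{parameter: float(val)})
        samples = sweep(cfg, n_samples, seed + j, bounds, **kwargs)
        surf = fit_surface(samples)
        surf.locate_optimum(bounds)
        out[float(val)] = surf
    return out


def capped_performance_experiment(config: EngagementConfig, n_samples: int,
                                  seed: int,
                                  cap_speed: float = 30.0,
                                  falcon: BirdMorphology = FALCON,
                                  **kwargs) -> pd.DataFrame:
    """Catch fractions with the falcon's load factor and/or roll
    acceleration capped at their sustained-level-flight (cap_speed) values.

    Runs the given attack geometry with no caps, each cap alone, and both
    caps, n_samples engagements each."""
    consts = kwargs.get("consts") or PhysicalConstants()
    p = falcon.to_vector(consts)
    from . import _kernel as k
    lf_cap = max(k.max_lift_gliding(cap_speed, p)[0], falcon.L0) / \
        (falcon.m_total * consts.g)
    roll_cap = k.max_roll_acceleration(cap_speed, p)[0]
    scenarios = {
        "uncapped": {},
        "roll_capped": {"roll_accel_cap": roll_cap},
        "load_capped": {"load_factor_cap": lf_cap},
        "both_capped": {"load_factor_cap": lf_cap,
                        "roll_accel_cap": roll_cap},
    }
    rows = []
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_samples)
    for name, caps in scenarios.items():
        cfg0 = config.replace(**caps)
        caught = 0
        for s in seeds:
            res = eng.run(cfg0.replace(seed=int(s)), falcon=falcon, **kwargs)
            caught += res.caught
        rows.append({"scenario": name, "n": n_samples,
                     "catch_fraction": caught / n_samples,
                     "load_factor_cap": cfg0.load_factor_cap,
                     "roll_accel_cap": cfg0.roll_accel_cap})
    return pd.DataFrame(rows)


def convergence_report(config: EngagementConfig, dts, **kwargs
                       ) -> pd.DataFrame:
    """Integration-step convergence: mean discrepancy between trajectories
    at dt and dt/10 with identical random seeding.

    For each quantity f, the discrepancy is the mean over common steps n of
    |f(dt/10) at step 10 n  -  f(dt) at step n|, truncated to the shortest
    run (no comparison beyond the first interception)."""
    dts = sorted(dts, reverse=True)
    runs = {}
    for dt in list(dts) + [dts[-1] / 10.0]:
        res = eng.run(config.replace(dt=dt), log_every=1, **kwargs)
        runs[dt] = res.trajectory
    rows = []
    for dt in dts:
        coarse = runs[dt]
        fine = runs[min(runs, key=lambda d: abs(d - dt / 10.0))]
        n = min(len(coarse), (len(fine) + 9) // 10)
        c = coarse.iloc[:n]
        f = fine.iloc[::10].iloc[:n]
        row = {"dt": dt}
        for col, name in [("distance", "distance"),
                          ("speed_falcon", "speed_predator"),
                          ("speed_prey", "speed_prey")]:
            row[name] = float(np.mean(np.abs(
                f[col].to_numpy() - c[col].to_numpy())))
        rows.append(row)
    return pd.DataFrame(rows)
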