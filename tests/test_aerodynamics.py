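"""Wingbeat-averaged force model: lift limits, thrust-minus-drag, optimal
retraction, roll performance, and the flight-performance envelope."""

import math

import numpy as np
import pytest

from stoopsim import _kernel as k
from stoopsim import aerodynamics as aero
from stoopsim.aerodynamics import WingConfig
from stoopsim.morphology import PhysicalConstants


def _grid_best_glide_td(L, v, p, n=10_000, with_torque=True):
    """Independent drag-minimizing span search at fixed achieved lift."""
    rho = p[k.IDX_RHO]
    best, b_best = -np.inf, None
    for b in np.linspace(p[k.IDX_BMIN] + 1e-9, p[k.IDX_BMAX], n):
        s = k.wing_area(b, p)
        cl = 2 * L / (s * rho * v * v) if s > 0 else (0.0 if L == 0 else np.inf)
        if cl > p[k.IDX_CLMAX] + 1e-12:
            continue
        if with_torque and L > 0 and \
                b > p[k.IDX_L0] * p[k.IDX_BMAX] / L + 1e-12:
            continue
        td = k.glide_td(L, b, v, p)
        if td > best:
            best, b_best = td, b
    return best, b_best


class TestTorqueCoefficient:
    def test_below_threshold_is_unity(self, falcon):
        assert aero.c_torque(0.5 * falcon.v_thresh, falcon.v_thresh) == 1.0

    def test_inverse_above_threshold(self, falcon):
        assert aero.c_torque(2 * falcon.v_thresh, falcon.v_thresh) == 0.5

    def test_continuity_at_threshold(self, falcon):
        vt = falcon.v_thresh
        lo = aero.c_torque(vt * (1 - 1e-9), vt)
        hi = aero.c_torque(vt * (1 + 1e-9), vt)
        assert lo == pytest.approx(hi, abs=1e-8)
        assert aero.c_torque(vt, vt) == 1.0

    def test_rejects_nonpositive_speed(self, falcon):
        with pytest.raises(ValueError):
            aero.c_torque(0.0, falcon.v_thresh)


class TestFrictionDrag:
    def test_quadrupling_re_halves_coefficient(self, falcon, consts):
        wing = WingConfig.at_span(falcon.b_max, falcon)
        c1 = aero.friction_drag_coeff(10.0, wing, falcon, consts)
        c4 = aero.friction_drag_coeff(40.0, wing, falcon, consts)
        assert c4 == pytest.approx(c1 / 2)

    def test_same_order_as_tabulated_constant(self, falcon, consts):
        # the tabulated reference value corresponds to a low flight speed
        wing = WingConfig.at_span(falcon.b_max, falcon)
        c = aero.friction_drag_coeff(6.0, wing, falcon, consts)
        assert 0.3 * falcon.c_d_fric_ref < c < 3 * falcon.c_d_fric_ref

    def test_fixed_mode_ignores_speed(self, falcon_fixed, consts):
        wing = WingConfig.at_span(falcon_fixed.b_max, falcon_fixed)
        for v in (5.0, 50.0):
            assert aero.friction_drag_coeff(v, wing, falcon_fixed, consts) \
                == falcon_fixed.c_d_fric_ref

    def test_degenerate_wing_returns_reference(self, falcon, consts):
        wing = WingConfig.at_span(falcon.b_min, falcon)
        assert wing.S_w == pytest.approx(0.0)
        assert aero.friction_drag_coeff(20.0, wing, falcon, consts) \
            == falcon.c_d_fric_ref


class TestMaxLiftGliding:
    def test_low_speed_clips_to_full_span(self, falcon, consts):
        l_max, b_ml = aero.max_lift_gliding(5.0, falcon, consts)
        assert b_ml == falcon.b_max
        stall = 0.5 * consts.rho * falcon.S_w_max * falcon.c_l_max * 25.0
        assert l_max == pytest.approx(min(falcon.L0, stall))

    def test_unclipped_stall_equals_torque_limited_lift(self, falcon,
                                                        consts):
        # at the interior optimum the stall-limited lift meets the
        # torque-limited lift (moment arm shrinking with retraction)
        for v in (30.0, 60.0, 120.0):
            l_max, b_ml = aero.max_lift_gliding(v, falcon, consts)
            assert falcon.b_min < b_ml < falcon.b_max
            stall = 0.5 * consts.rho * falcon.S_w_max \
                * (b_ml - falcon.b_min) / (falcon.b_max - falcon.b_min) \
                * falcon.c_l_max * v * v
            torque = falcon.L0 * (falcon.b_max - falcon.b_min) \
                / (b_ml - falcon.b_min)
            assert l_max == pytest.approx(stall, rel=1e-9)
            assert l_max == pytest.approx(torque, rel=1e-9)

    @pytest.mark.parametrize("v", [5.0, 10.0, 20.0, 40.0, 80.0, 120.0])
    def test_matches_grid_search_oracle(self, v, falcon, consts):
        """Closed form vs brute-force max of min(stall, torque-limited)
        lift over a 10^4-point span grid, to < 0.1%."""
        p = falcon.to_vector(consts)
        grid = np.linspace(falcon.b_min + 1e-6, falcon.b_max, 10_000)
        stall = np.array([0.5 * consts.rho * k.wing_area(b, p)
                          * falcon.c_l_max * v * v for b in grid])
        torque = falcon.L0 * (falcon.b_max - falcon.b_min) \
            / (grid - falcon.b_min)
        torque[-1] = falcon.L0  # full span: torque cap is L0 itself
        best = np.max(np.minimum(stall, np.minimum(torque, np.where(
            grid >= falcon.b_max - 1e-9, falcon.L0, np.inf))))
        l_max, _ = aero.max_lift_gliding(v, falcon, consts)
        assert l_max == pytest.approx(best, rel=1e-3)


class TestOptimalGlideSpan:
    def test_zero_lift_retracts_fully(self, falcon, consts):
        b, sat = aero.optimal_glide_span(0.0, 10.0, falcon, consts)
        assert b == falcon.b_min
        assert not sat

    def test_torque_bound_governs_large_lift_at_moderate_speed(self, falcon,
                                                               consts):
        v = 20.0
        l_max, _ = aero.max_lift_gliding(v, falcon, consts)
        L = 0.9 * l_max
        b, sat = aero.optimal_glide_span(L, v, falcon, consts)
        assert not sat
        assert b == pytest.approx(falcon.L0 * falcon.b_max / L, rel=1e-6)

    def test_saturation_returns_max_lift_span(self, falcon, consts):
        v = 30.0
        l_max, b_ml = aero.max_lift_gliding(v, falcon, consts)
        b, sat = aero.optimal_glide_span(2 * l_max, v, falcon, consts)
        assert sat and b == pytest.approx(b_ml)

    @pytest.mark.parametrize("v,frac", [
        (10.0, 0.1), (10.0, 0.5), (10.0, 0.9),
        (20.0, 0.1), (20.0, 0.6), (20.0, 0.9),
        (40.0, 0.1), (40.0, 0.3),
        (80.0, 0.1), (80.0, 0.3),
        (120.0, 0.1), (120.0, 0.3),
    ])
    def test_net_thrust_matches_grid_oracle(self, v, frac, falcon_fixed,
                                            consts):
        """Achieved net thrust within 0.1% of a fine span-grid maximum,
        over the regime where the span truncation rules are mutually
        consistent (below the torque/stall conflict threshold)."""
        p = falcon_fixed.to_vector(consts)
        l_max, _ = k.max_lift_gliding(v, p)
        L = frac * l_max
        b = k.optimal_glide_span(L, v, p)
        td = k.glide_td(L, b, v, p)
        best, _ = _grid_best_glide_td(L, v, p)
        assert td >= best - 1e-3 * abs(best)

    def test_conflict_regime_rides_stall_boundary(self, falcon_fixed,
                                                  consts):
        # when the torque span cap is incompatible with producing L at
        # all, the cascade falls back to the smallest span that avoids
        # stall (lift coefficient exactly at its maximum)
        p = falcon_fixed.to_vector(consts)
        v = 80.0
        L = 0.6 * k.max_lift_gliding(v, p)[0]
        b = k.optimal_glide_span(L, v, p)
        s = k.wing_area(b, p)
        cl = 2 * L / (s * consts.rho * v * v)
        assert cl == pytest.approx(falcon_fixed.c_l_max, rel=1e-9)


class TestThrustMinusDrag:
    def test_max_lift_coefficient_kills_flapping_thrust(self, falcon,
                                                        consts):
        wing = WingConfig.at_span(falcon.b_max, falcon, flapping=True)
        td = aero.thrust_minus_drag(falcon.c_l_max, wing, 15.0, falcon,
                                    consts)
        # thrust term is exactly zero, so only drag remains
        assert td < 0

    def test_gliding_fully_retracted_leaves_body_drag(self, falcon, consts):
        wing = WingConfig.at_span(falcon.b_min, falcon)
        v = 30.0
        td = aero.thrust_minus_drag(0.0, wing, v, falcon, consts)
        body = falcon.c_d_body * falcon.S_b * 0.5 * consts.rho * v * v
        assert td == pytest.approx(-body)

    def test_rejects_excess_lift_coefficient(self, falcon, consts):
        wing = WingConfig.at_span(falcon.b_max, falcon, flapping=True)
        with pytest.raises(ValueError):
            aero.thrust_minus_drag(1.01 * falcon.c_l_max, wing, 15.0,
                                   falcon, consts)

    def test_concave_quadratic_in_lift_when_flapping(self, falcon, consts):
        p = falcon.to_vector(consts)
        v = 15.0
        L = np.linspace(0.0, falcon.L0, 30)
        td = np.array([k.flap_td(x, v, p) for x in L])
        d2 = np.diff(td, 2)
        assert np.all(d2 < 0)
        # quadratic: second difference constant
        assert np.allclose(d2, d2[0], rtol=1e-6)


class TestResolveForces:
    def test_deterministic_without_control_error(self, falcon, consts):
        a = aero.resolve_forces(3.0, 20.0, falcon, consts)
        b = aero.resolve_forces(3.0, 20.0, falcon, consts)
        assert a == b

    def test_saturation_reports_max_attainable(self, falcon, consts):
        v = 25.0
        res = aero.resolve_forces(1e4, v, falcon, consts)
        assert res.saturated
        l_glide, _ = aero.max_lift_gliding(v, falcon, consts)
        assert res.L == pytest.approx(max(l_glide, falcon.L0), rel=1e-6)

    def test_glide_wins_at_high_speed_with_modest_lift(self, falcon,
                                                       consts):
        res = aero.resolve_forces(falcon.weight, 60.0, falcon, consts)
        assert not res.wing.flapping
        # direct comparison of the two modes' net thrust
        p = falcon.to_vector(consts)
        assert res.TD > k.flap_td(falcon.weight, 60.0, p)

    def test_flap_wins_when_climbing_at_cruise(self, falcon, consts):
        # at cruise speed with weight-level lift, flapping thrust is the
        # only positive-TD option
        res = aero.resolve_forces(falcon.weight, 15.0, falcon, consts)
        assert res.wing.flapping and res.TD > 0

    def test_achieved_lift_never_exceeds_mode_limits(self, falcon, consts):
        p = falcon.to_vector(consts)
        for v in (8.0, 15.0, 40.0, 100.0):
            for ld in (0.1, 1.0, 5.0, 50.0, 500.0):
                L, td, mode, cl, b, sat = k.resolve_forces(ld, v, p)
                assert L <= ld + 1e-9
                lim = k.flap_max_lift(v, p) if mode == k.MODE_FLAP \
                    else k.max_lift_gliding(v, p)[0]
                assert L <= lim + 1e-9


class TestRollPerformance:
    @pytest.mark.parametrize("v", [5.0, 15.0, 40.0, 90.0, 120.0])
    def test_roll_optimal_span_is_max_lift_span(self, v, falcon, consts):
        """Brute force over spans: torque/inertia is maximized at the span
        that maximizes lift."""
        p = falcon.to_vector(consts)
        om_k = k.max_roll_acceleration(v, p)[0]
        best = 0.0
        for b in np.linspace(falcon.b_min + 1e-6, falcon.b_max, 4000):
            stall = 0.5 * consts.rho * k.wing_area(b, p) \
                * falcon.c_l_max * v * v
            torque_lim = falcon.L0 * (falcon.b_max - falcon.b_min) \
                / (b - falcon.b_min)
            L = min(stall, torque_lim)
            om = (L * b / 4.0) / k.roll_inertia(b / falcon.b_max, p)
            best = max(best, om)
        assert om_k == pytest.approx(best, rel=5e-3)

    def test_scaling_with_speed_below_truncation(self, starling, consts):
        # in the full-span (clipped) regime lift grows with v^2 at fixed
        # inertia, so roll acceleration does too
        a1 = aero.max_roll_acceleration(3.0, starling, consts)
        a2 = aero.max_roll_acceleration(6.0, starling, consts)
        assert a2 == pytest.approx(4 * a1, rel=1e-6)

    def test_starling_outrolls_falcon_at_low_speed(self, falcon, starling,
                                                   consts):
        for v in (5.0, 10.0, 20.0):
            assert aero.max_roll_acceleration(v, starling, consts) > \
                aero.max_roll_acceleration(v, falcon, consts)

    def test_falcon_matches_starling_peak_only_in_fast_dive(self, falcon,
                                                            starling,
                                                            consts):
        grid = np.linspace(2, aero.max_level_speed(starling, consts), 120)
        starling_peak = max(aero.max_roll_acceleration(v, starling, consts)
                            for v in grid)
        assert aero.max_roll_acceleration(45.0, falcon, consts) \
            < starling_peak
        v_term = aero.terminal_dive_speed(falcon, consts)
        assert aero.max_roll_acceleration(v_term, falcon, consts) \
            > starling_peak


class TestPerformanceEnvelope:
    def test_deterministic_and_definitional_radius(self, falcon, consts):
        grid = np.linspace(5, 120, 40)
        e1 = aero.performance_envelope(falcon, consts, grid)
        e2 = aero.performance_envelope(falcon, consts, grid)
        assert np.array_equal(e1.level_acceleration, e2.level_acceleration)
        assert np.array_equal(e1.roll_acceleration, e2.roll_acceleration)
        np.testing.assert_allclose(
            e1.turning_radius, grid**2 / (e1.load_factor * consts.g))

    def test_speed_orderings_between_species(self, falcon, starling,
                                             consts):
        assert aero.max_level_speed(falcon, consts) > \
            aero.max_level_speed(starling, consts)
        assert aero.terminal_dive_speed(falcon, consts) > \
            aero.terminal_dive_speed(starling, consts)
        assert aero.min_level_speed(falcon, consts) > \
            aero.min_level_speed(starling, consts)

    def test_rejects_bad_grid(self, falcon, consts):
        with pytest.raises(ValueError):
            aero.performance_envelope(falcon, consts, np.array([]))
        with pytest.raises(ValueError):
            aero.performance_envelope(falcon, consts, np.array([5.0, 4.0]))

    def test_csv_export_roundtrip(self, falcon, consts, tmp_path):
        import pandas as pd

        env = aero.performance_envelope(falcon, consts,
                                        np.linspace(5, 50, 10))
        path = tmp_path / "env.csv"
        env.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["speed", "level_acceleration",
                                    "dive_acceleration", "load_factor",
                                    "roll_acceleration", "turning_radius"]
        np.testing.assert_allclose(df["speed"], env.speed)
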