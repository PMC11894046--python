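import math

import numpy as np
import pytest

from dmdsim import (
    Direction,
    InfeasibleOrderError,
    MirrorGeometry,
    cost,
    exact_solution_condition,
    inplane_angle_to_direction,
    solve_family,
    solve_inplane,
    specular_direction,
    two_color_compromise,
)
from dmdsim.blaze_solver import family_to_frame
from dmdsim.diffraction import output_direction


def grid_search_inplane(order, lam_nm, geom, state, step_deg=0.001):
    """Independent oracle: dense scan of in-plane incidence minimizing the cost."""
    nx, _ = order
    ld = lam_nm * 1e-3 / geom.pitch_um
    thetas = np.arange(0.0, 90.0, step_deg)
    ax = np.sin(np.radians(thetas))
    bx = ax + nx * ld
    ok = np.abs(bx) < 1.0
    thetas, ax, bx = thetas[ok], ax[ok], bx[ok]
    az = -np.sqrt(1 - ax**2)
    bz = np.sqrt(1 - bx**2)
    R = geom.rotation(state)
    d1 = (bx - ax) * R[0, 0] + (bz - az) * R[2, 0]
    d2 = (bx - ax) * R[0, 1] + (bz - az) * R[2, 1]
    c = d1**2 + d2**2
    i = int(np.argmin(c))
    return thetas[i], c[i]


class TestCost:
    def test_zero_at_specular(self, trp):
        a = Direction.incoming(0.55, 0.1)
        b = specular_direction(a, trp.mirror_normal("-"))
        assert cost(a, b, trp, "-") == pytest.approx(0.0, abs=1e-15)

    def test_retroreflection_on_flat_mirror(self):
        flat = MirrorGeometry(pitch_um=5.4, axis_plus=(1, 0, 0), axis_minus=(0, 1, 0),
                              gamma_plus_deg=1e-9, gamma_minus_deg=1e-9)
        a = Direction.incoming(0.3, 0.2)
        b = Direction.outgoing(0.3, 0.2)  # b = -a up to the z sign flip: b_xy = a_xy
        # for a flat mirror the frame is the backplane frame: b1-a1 = 0 here,
        # so use the reversed beam instead (true retro-reflection)
        retro = Direction.outgoing(-0.3, -0.2)
        assert cost(a, retro, flat, "-") == pytest.approx(4 * (0.3**2 + 0.2**2), abs=1e-9)
        assert cost(a, b, flat, "-") == pytest.approx(0.0, abs=1e-12)

    def test_inplane_optimum_beats_random_feasible_pairs(self, trp, rng):
        sol = solve_inplane((-5, 0), 488.0, trp, "-")
        ld = 0.488 / trp.pitch_um
        n = 10_000
        ax = rng.uniform(-1, 1, n)
        ay = rng.uniform(-1, 1, n)
        bx, by = ax - 5 * ld, ay
        ok = (ax**2 + ay**2 < 1) & (bx**2 + by**2 < 1)
        R = trp.rotation("-")
        az = -np.sqrt(1 - ax[ok] ** 2 - ay[ok] ** 2)
        bz = np.sqrt(1 - bx[ok] ** 2 - by[ok] ** 2)
        du = np.stack([bx[ok] - ax[ok], by[ok] - ay[ok], bz - az])
        c = (R[:, 0] @ du) ** 2 + (R[:, 1] @ du) ** 2
        assert sol.cost <= c.min() + 1e-9


class TestExactSolutionCondition:
    def test_cip_diagonal_orders(self, cip):
        rep = exact_solution_condition(cip, "+")
        assert rep.ratio == pytest.approx(-1.0, abs=1e-12)
        assert all(o.n_x == -o.n_y for o in rep.orders)
        assert len(rep.orders) > 0

    def test_trp_has_none(self, trp):
        rep = exact_solution_condition(trp, "-")
        assert rep.ratio == pytest.approx(90.523, abs=5e-4)
        assert rep.orders == ()

    def test_flat_mirror_specular_only(self):
        flat = MirrorGeometry(pitch_um=5.4, axis_plus=(1, 0, 0), axis_minus=(0, 1, 0),
                              gamma_plus_deg=1e-10, gamma_minus_deg=1e-10)
        rep = exact_solution_condition(flat, "-")
        assert rep.orders == ((0, 0),)

    def test_inplane_axis_reports_infinite_ratio(self):
        geom = MirrorGeometry(pitch_um=5.4, axis_plus=(1, 0, 0), axis_minus=(0, -1, 0),
                              gamma_plus_deg=17, gamma_minus_deg=17)
        rep = exact_solution_condition(geom, "-")
        assert math.isinf(rep.ratio)
        assert all(o.n_y == 0 for o in rep.orders)


class TestInplane:
    @pytest.mark.parametrize(
        "order,lam,inc,out,db",
        [
            ((-5, 0), 488.0, 55.9, 22.1, 0.29),
            ((-4, 0), 635.0, 52.9, 19.1, 0.3),
            ((-6, 0), 488.0, 38.1, 4.3, 0.34),
        ],
    )
    def test_printed_two_color_solutions(self, trp, order, lam, inc, out, db):
        sol = solve_inplane(order, lam, trp, "-")
        assert sol.incidence_deg == pytest.approx(inc, abs=0.05)
        assert sol.output_deg == pytest.approx(out, abs=0.05)
        assert sol.delta_b_deg == pytest.approx(db, abs=0.05)

    @pytest.mark.parametrize("order,lam", [((-5, 0), 488.0), ((-4, 0), 635.0), ((-6, 0), 488.0)])
    def test_agrees_with_dense_grid_oracle(self, trp, order, lam):
        theta, _ = grid_search_inplane(order, lam, trp, "-", step_deg=0.001)
        sol = solve_inplane(order, lam, trp, "-")
        assert sol.incidence_deg == pytest.approx(theta, abs=0.01)

    def test_plus_state_mirror_symmetry(self, trp):
        minus = solve_inplane((-5, 0), 488.0, trp, "-")
        plus = solve_inplane((0, -5), 488.0, trp, "+")
        assert plus.incidence_deg == pytest.approx(minus.incidence_deg, abs=1e-6)
        assert plus.delta_b_deg == pytest.approx(minus.delta_b_deg, abs=1e-6)

    def test_wrong_order_type_rejected(self, trp):
        with pytest.raises(ValueError):
            solve_inplane((-5, 1), 488.0, trp, "-")

    def test_evanescent_order_rejected(self, trp):
        with pytest.raises(InfeasibleOrderError):
            solve_inplane((-25, 0), 635.0, trp, "-")

    def test_output_angle_matches_rational_ratio_prediction(self, trp):
        # the output's mirror-frame normal component tracks n_x lambda/(2 R13 d)
        R = trp.rotation("-")
        for order, lam in [((-5, 0), 488.0), ((-6, 0), 488.0), ((-4, 0), 635.0)]:
            sol = solve_inplane(order, lam, trp, "-")
            b3 = float(sol.b.as_array() @ R[:, 2])
            pred = order[0] * (lam * 1e-3) / (2 * R[0, 2] * trp.pitch_um)
            assert math.degrees(math.acos(min(1, b3))) == pytest.approx(
                math.degrees(math.acos(min(1, pred))), abs=0.5
            )


class TestFamily:
    def test_constraints_and_stationarity(self, trp):
        fam = solve_family((-5, 0), 488.0, trp, "-", n_points=60)
        ld = 0.488 / trp.pitch_um
        costs = [s.cost for s in fam]
        for s in fam:
            assert s.b.x - s.a.x == pytest.approx(-5 * ld, abs=1e-12)
            assert s.b.y - s.a.y == pytest.approx(0.0, abs=1e-12)
            assert _lagrangian_gradient_norm(s, trp) < 1e-6
        # the whole family is cost-optimal: constant cost along the curve
        assert max(costs) - min(costs) < 1e-10

    def test_family_cost_beats_random_search(self, trp, rng):
        fam = solve_family((0, -5), 488.0, trp, "+", n_points=30)
        ld = 0.488 / trp.pitch_um
        n = 200_000
        ax, ay = rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)
        bx, by = ax, ay - 5 * ld
        ok = (ax**2 + ay**2 < 1) & (bx**2 + by**2 < 1)
        R = trp.rotation("+")
        az = -np.sqrt(1 - ax[ok] ** 2 - ay[ok] ** 2)
        bz = np.sqrt(1 - bx[ok] ** 2 - by[ok] ** 2)
        du = np.stack([bx[ok] - ax[ok], by[ok] - ay[ok], bz - az])
        c = (R[:, 0] @ du) ** 2 + (R[:, 1] @ du) ** 2
        assert min(s.cost for s in fam) <= c.min() + 1e-6

    def test_innermost_curve_is_highest_order(self, trp):
        areas = {}
        for n in (-4, -5, -6):
            fam = solve_family((0, n), 488.0, trp, "+", n_points=180)
            pts = np.array([[s.b.x, s.b.y] for s in fam])
            x, y = pts[:, 0], pts[:, 1]
            areas[n] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert areas[-6] < areas[-5] < areas[-4]

    def test_red_high_orders_collapse_to_points(self, trp):
        for n in (-6, -5):
            fam = solve_family((0, n), 635.0, trp, "+")
            assert len(fam) == 1 and fam[0].degenerate
        fam4 = solve_family((0, -4), 635.0, trp, "+", n_points=90)
        assert len(fam4) == 90

    def test_cip_exact_orders_reach_zero_violation(self, cip):
        fam = solve_family((3, -3), 488.0, cip, "+", n_points=720)
        assert min(s.delta_b_deg for s in fam) < 0.02
        assert min(s.cost for s in fam) < 1e-8

    def test_infeasible_order(self, trp):
        with pytest.raises(InfeasibleOrderError):
            solve_family((-20, 0), 635.0, trp, "-")

    def test_family_parameter_monotone(self, trp):
        fam = solve_family((-5, 0), 488.0, trp, "-", n_points=50)
        params = [s.family_parameter for s in fam]
        assert params == sorted(params)
        assert 0.0 <= params[0] and params[-1] < 1.0

    def test_frame_export(self, trp):
        df = family_to_frame(solve_family((-5, 0), 488.0, trp, "-", n_points=10))
        assert {"b_x", "b_y", "delta_b_deg", "n_x", "n_y", "wavelength_nm", "state"} <= set(
            df.columns
        )


def _lagrangian_gradient_norm(sol, geom, eps=1e-7):
    """Numerical gradient of the Lagrangian at a solution (all four variables)."""
    alpha, beta = sol.multipliers
    ld = sol.wavelength_nm * 1e-3 / geom.pitch_um
    nu = (sol.order.n_x * ld, sol.order.n_y * ld)

    def lagrangian(ax, ay, bx, by):
        a = Direction.incoming(ax, ay)
        b = Direction.outgoing(bx, by)
        return (
            alpha * (bx - ax - nu[0])
            + beta * (by - ay - nu[1])
            + cost(a, b, geom, sol.state)
        )

    x0 = np.array([sol.a.x, sol.a.y, sol.b.x, sol.b.y])
    g = []
    for i in range(4):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += eps
        xm[i] -= eps
        g.append((lagrangian(*xp) - lagrangian(*xm)) / (2 * eps))
    return float(np.linalg.norm(g))


class TestTwoColor:
    def test_printed_realignment_values(self, trp):
        anchor = solve_inplane((-5, 0), 488.0, trp, "-")
        second, _ = two_color_compromise(anchor, 635.0, (-4, 0), trp, contrast=False)
        assert second.incidence_deg == pytest.approx(57.9, abs=0.05)
        assert second.delta_b_deg == pytest.approx(1.97, abs=0.05)

    def test_printed_low_tilt_realignment(self, trp):
        anchor = solve_inplane((-6, 0), 488.0, trp, "-")
        second, _ = two_color_compromise(anchor, 635.0, (-5, 0), trp, contrast=False)
        assert second.incidence_deg == pytest.approx(41.6, abs=0.05)
        assert second.delta_b_deg == pytest.approx(3.4, abs=0.05)

    def test_idempotent_for_same_color(self, trp):
        anchor = solve_inplane((-5, 0), 488.0, trp, "-")
        same, _ = two_color_compromise(anchor, 488.0, (-5, 0), trp, contrast=False)
        assert same.incidence_deg == pytest.approx(anchor.incidence_deg, abs=1e-12)
        assert same.delta_b_deg == pytest.approx(anchor.delta_b_deg, abs=1e-12)

    def test_output_directions_match(self, trp):
        anchor = solve_inplane((-6, 0), 488.0, trp, "-")
        second, _ = two_color_compromise(anchor, 635.0, (-5, 0), trp, contrast=False)
        assert (second.b.x, second.b.y) == (anchor.b.x, anchor.b.y)
        b_check = output_direction(second.a, (-5, 0), 635.0, trp.pitch_um)
        # acos near 1 limits the angle resolution to ~1e-6 deg
        assert b_check.angle_to(anchor.b) == pytest.approx(0.0, abs=1e-5)

    def test_contrast_chain_orders_colors(self, trp):
        anchor = solve_inplane((-6, 0), 488.0, trp, "-")
        _, recs = two_color_compromise(anchor, 635.0, (-5, 0), trp)
        assert set(recs) == {488.0, 635.0}
        for rec in recs.values():
            assert 0.0 <= rec.eta <= 1.0
            assert rec.m == pytest.approx(2 * rec.eta / (1 + rec.eta**2))
        # the realigned color violates the blaze condition more, so its
        # suborders are more imbalanced
        assert recs[635.0].eta < recs[488.0].eta

    def test_unreachable_output(self, trp):
        anchor = solve_inplane((-5, 0), 488.0, trp, "-")
        with pytest.raises(InfeasibleOrderError, match="physical"):
            two_color_compromise(anchor, 635.0, (20, 0), trp, contrast=False)
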