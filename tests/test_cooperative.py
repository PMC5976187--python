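"""Cooperative correction: constraints, best-path selection, method variants."""

import numpy as np
import pytest

import vesseltrace as vt
from vesseltrace import cooperative as coop
from vesseltrace.marching import ActionMap, afm

from conftest import mean_pairwise_distance, min_distance_beyond_kappa


def fake_action(u_value: float, shape=(5, 5, 5)) -> ActionMap:
    U = np.full(shape, u_value)
    vol = vt.Volume(U, (1, 1, 1), allow_infinite=True)
    return ActionMap(U=vol, alive=np.ones(shape, dtype=bool), source=np.zeros(3))


def straight_path(length_mm: float, step: float = 0.1, z: float = 0.0):
    n = int(round(length_mm / step)) + 1
    pts = np.column_stack([np.arange(n) * step, np.zeros(n), np.full(n, z)])
    return vt.Centerline(pts, step)


class TestAveragePathCost:
    def test_division(self):
        a = fake_action(10.0, shape=(25, 5, 5))
        path = straight_path(20.0)
        assert coop.average_path_cost(a, path) == pytest.approx(0.5)

    def test_uniform_cost_gives_cost_per_mm(self):
        v = vt.Volume(np.full((41, 11, 11), 3.0), (0.5, 0.5, 0.5))
        path, action = afm(v, (1, 2.5, 2.5), (18, 2.5, 2.5), 0.1)
        assert coop.average_path_cost(action, path) == pytest.approx(3.0, rel=0.05)

    def test_comparison_prefers_lower_average(self):
        a = fake_action(10.0, shape=(25, 5, 5))
        b = fake_action(9.0, shape=(25, 5, 5))
        assert coop.average_path_cost(a, straight_path(20.0)) < coop.average_path_cost(
            b, straight_path(10.0)
        )

    def test_non_alive_endpoint_rejected(self):
        a = fake_action(1.0)
        a.alive[:, :, :] = False
        a.U.data[:] = np.inf
        with pytest.raises(ValueError):
            coop.average_path_cost(a, straight_path(4.0))


class TestSelectBest:
    def test_order_and_tiebreak(self):
        act = fake_action(10.0, shape=(25, 5, 5))
        short, long = straight_path(10.0), straight_path(20.0)
        best, neigh = coop.select_best(short, long, act)  # avg 1.0 vs 0.5
        assert best is long and neigh is short
        best2, _ = coop.select_best(long, short, act)
        assert best2 is long
        # exact tie breaks toward the first argument
        tie_a, tie_b = straight_path(10.0), straight_path(10.0)
        best3, _ = coop.select_best(tie_a, tie_b, act)
        assert best3 is tie_a


class TestConstraintStart:
    def test_exact_point(self):
        p = straight_path(10.0)
        assert coop.constraint_start(p, p.points[37]) == 37

    def test_tie_earliest(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 2, 0]], dtype=float)
        path = vt.Centerline(pts, 2.0)
        # (1, 1, 0) is at distance 1 from both index 1 and index 3
        assert coop.constraint_start(path, (1.0, 1.0, 0.0)) == 1

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        p = straight_path(10.0)
        for _ in range(20):
            x = rng.uniform(-2, 12, 3)
            d = np.linalg.norm(p.points - x, axis=1)
            assert coop.constraint_start(p, x) == int(np.argmin(d))


class TestBuildApplyConstraint:
    def grid(self):
        return vt.Volume(np.ones((12, 10, 8)), (0.5, 0.5, 0.9))

    def test_empty_segment_empty_mask(self):
        p = straight_path(3.0)
        k = coop.build_constraint(p, p.points.shape[0], 1.75, self.grid(), K=99.0)
        assert k.is_empty()

    def test_radius_threshold(self):
        g = self.grid()
        pts = np.array([[2.0, 2.0, 1.8], [2.1, 2.0, 1.8]])
        path = vt.Centerline(pts, 0.1)
        k = coop.build_constraint(path, 0, 1.75, g, K=99.0)
        near = g.nearest_voxel((3.0, 2.0, 1.8))  # 1.0 mm from a path point
        far = g.nearest_voxel((4.5, 2.0, 1.8))  # 2.4 mm away
        assert k.mask[near]
        assert not k.mask[far]

    def test_mask_matches_bruteforce(self):
        g = self.grid()
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(-0.05, 0.1, size=(30, 3)), axis=0) + [2.5, 2.5, 3.0]
        path = vt.Centerline(pts, 0.2)
        rho = 1.2
        k = coop.build_constraint(path, 10, rho, g, K=1.0)
        xs, ys, zs = g.axes_mm()
        centers = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        brute = np.zeros(g.shape, dtype=bool)
        for q in pts[10:]:
            brute |= np.linalg.norm(centers - q, axis=-1) <= rho
        assert np.array_equal(k.mask, brute)

    def test_exclusion_ball(self):
        g = self.grid()
        path = vt.Centerline(np.array([[2.0, 2.0, 1.8], [2.1, 2.0, 1.8]]), 0.1)
        excl = (2.0, 2.0, 1.8)
        k = coop.build_constraint(path, 0, 1.75, g, K=1.0, exclude=[excl])
        assert not k.mask[g.nearest_voxel(excl)]

    def test_apply_is_exact_masked_replacement(self):
        g = self.grid()
        path = vt.Centerline(np.array([[2.0, 2.0, 1.8], [2.1, 2.0, 1.8]]), 0.1)
        k = coop.build_constraint(path, 0, 1.0, g, K=123.5)
        out = coop.apply_constraint(g, k)
        assert np.all(out.data[k.mask] == 123.5)
        assert np.array_equal(out.data[~k.mask], g.data[~k.mask])
        empty = coop.build_constraint(path, 2, 1.0, g, K=123.5)
        assert np.array_equal(coop.apply_constraint(g, empty).data, g.data)

    def test_grid_mismatch(self):
        g = self.grid()
        path = vt.Centerline(np.array([[2.0, 2.0, 1.8], [2.1, 2.0, 1.8]]), 0.1)
        k = coop.build_constraint(path, 0, 1.0, g, K=1.0)
        other = vt.Volume(np.ones((5, 5, 5)), (1, 1, 1))
        with pytest.raises(ValueError):
            coop.apply_constraint(other, k)


class TestShiftBifurcation:
    def uniform(self):
        return vt.Volume(np.ones((51, 11, 11)), (0.5, 0.5, 0.5))

    def test_zero_shift_returns_gap_point(self):
        v = self.uniform()
        out = coop.shift_bifurcation(v, (1, 2.5, 2.5), (21, 2.5, 2.5), t=0.0)
        assert np.linalg.norm(out - (21, 2.5, 2.5)) < 0.1

    def test_straight_path_arc_arithmetic(self):
        v = self.uniform()
        out = coop.shift_bifurcation(v, (1, 2.5, 2.5), (21, 2.5, 2.5), t=5.1)
        assert np.linalg.norm(out - (15.9, 2.5, 2.5)) <= 0.1 + 0.05

    def test_excessive_shift_rejected(self):
        v = self.uniform()
        with pytest.raises(ValueError):
            coop.shift_bifurcation(v, (1, 2.5, 2.5), (5, 2.5, 2.5), t=50.0)

    def test_shifted_seed_lands_inside_vessel(self, clean_bundle):
        """Pulling the gap point back along the CCA path must land inside
        the lumen near the centerline bifurcation."""
        b = clean_bundle
        out = coop.shift_bifurcation(b.cost.p_tilde, b.seeds.x_C, b.seeds.x_BIF, t=5.1)
        d = min(
            vt.point_to_path(out, b.truth.centerline_ICA),
            vt.point_to_path(out, b.truth.centerline_ECA),
        )
        assert d < min(b.spec.branch_radii)
        assert out[2] < b.seeds.x_BIF[2]  # strictly proximal of the gap point


class TestEstimateBifurcation:
    def test_identical_paths_distal_endpoint(self):
        p = straight_path(10.0)
        out = coop.estimate_bifurcation(p, vt.Centerline(p.points.copy(), p.step))
        assert np.allclose(out, p.points[-1])

    def test_converging_lines_analytic(self):
        # two lines through the origin at +-20 degrees, walked from far ends
        delta, tol, half = 0.1, 1.0, np.deg2rad(20)
        s = np.arange(0, 30.0001, delta)
        a = np.column_stack([s * np.cos(half), s * np.sin(half), np.zeros_like(s)])
        b = np.column_stack([s * np.cos(half), -s * np.sin(half), np.zeros_like(s)])
        ca = vt.Centerline(a, delta)
        cb = vt.Centerline(b, delta)
        out = coop.estimate_bifurcation(ca, cb, tol=tol)
        # inter-line distance of a point at arc s is s*sin(2*half)
        s_star = tol / np.sin(2 * half)
        expected = np.array([s_star * np.cos(half), 0.0, 0.0])
        assert np.linalg.norm(out - expected) <= 2 * delta + 0.05

    def test_never_converging_errors(self):
        a = straight_path(10.0, z=0.0)
        b = straight_path(10.0, z=5.0)
        with pytest.raises(ValueError):
            coop.estimate_bifurcation(a, b, tol=1.0)


class TestMethods:
    @pytest.mark.parametrize("method", coop.METHODS)
    def test_endpoints_contract(self, clean_bundle, method):
        r = clean_bundle.result(method)
        s = clean_bundle.seeds
        for path, end in ((r.centerline_ICA, s.x_I), (r.centerline_ECA, s.x_E)):
            assert np.linalg.norm(path.points[0] - s.x_C) < 0.1 + 1e-9
            assert np.linalg.norm(path.points[-1] - end) < 0.1 + 1e-9

    def test_scbie_passes_through_shifted_seed(self, clean_bundle):
        r = clean_bundle.result("SCBIE")
        x_s = np.asarray(r.diagnostics["x_BIF_s"])
        for path in (r.centerline_ICA, r.centerline_ECA):
            d = np.linalg.norm(path.points - x_s, axis=1).min()
            assert d < 1e-9

    def test_cooperative_inactive_when_paths_separate(self, clean_bundle):
        scie = clean_bundle.result("SCIE")
        ccie = clean_bundle.result("CCIE")
        diag = np.linalg.norm(clean_bundle.cost.p.spacing)
        assert vt.hausdorff(scie.centerline_ICA, ccie.centerline_ICA) <= diag
        assert vt.hausdorff(scie.centerline_ECA, ccie.centerline_ECA) <= diag

    def test_faint_phantom_collapse_and_fix(self, faint_bundle):
        b = faint_bundle
        zb = b.spec.bifurcation_z
        scie = b.result("SCIE")
        assert mean_pairwise_distance(scie.centerline_ICA, scie.centerline_ECA, zb) < 1.0
        ccie = b.result("CCIE")
        assert (
            min_distance_beyond_kappa(ccie, b.seeds.x_BIF)
            >= ccie.diagnostics["rho"] - 1e-9
        )

    def test_corrected_paths_avoid_constraints(self, faint_bundle):
        for method in ("CCIE", "CCBIE"):
            d = faint_bundle.result(method).diagnostics
            assert d["neighbour_enters_kappa"] is False
            assert d["best_enters_kappa"] is False

    def test_method_results_deterministic(self, faint_bundle):
        r1 = coop.run_method("CCIE", faint_bundle.cost, faint_bundle.seeds)
        r2 = coop.run_method("CCIE", faint_bundle.cost, faint_bundle.seeds)
        assert np.array_equal(r1.centerline_ICA.points, r2.centerline_ICA.points)
        assert np.array_equal(r1.centerline_ECA.points, r2.centerline_ECA.points)

    def test_missing_bifurcation_seed_rejected(self, clean_bundle):
        seeds = vt.SeedSet(
            clean_bundle.seeds.x_C, clean_bundle.seeds.x_I, clean_bundle.seeds.x_E
        )
        with pytest.raises(ValueError):
            coop.run_method("CCIE", clean_bundle.cost, seeds)

    def test_unknown_method_rejected(self, clean_bundle):
        with pytest.raises(ValueError):
            coop.run_method("XXX", clean_bundle.cost, clean_bundle.seeds)
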