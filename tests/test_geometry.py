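"""Geometric primitives: plane construction, sphere/axis fitting, projections.

Fits are checked against independent brute-force least-squares oracles run
inside the tests, never against the implementation itself.
"""

import numpy as np
import pytest
from scipy.optimize import least_squares, minimize
from scipy.spatial.transform import Rotation

from coxaplan.geometry import (
    DegenerateInputError,
    Line,
    ParallelLinesError,
    closest_approach,
    fit_axis,
    fit_sphere,
    plane_from_points,
    projected_angle,
)


class TestPlaneFromPoints:
    def test_canonical_plane(self):
        pl = plane_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert np.allclose(pl.normal, [0, 0, 1])
        assert pl.contains([0.3, 0.4, 0.0])

    @pytest.mark.parametrize("pts", [
        ([0, 0, 0], [1, 1, 1], [2, 2, 2]),          # collinear
        ([1, 2, 3], [1, 2, 3], [4, 5, 6]),          # duplicate
    ])
    def test_degenerate_inputs(self, pts):
        with pytest.raises(DegenerateInputError):
            plane_from_points(*pts)

    def test_cyclic_invariance_and_swap_flip(self, rng):
        pts = rng.normal(size=(3, 3)) * 20
        base = plane_from_points(*pts)
        cyc = plane_from_points(pts[1], pts[2], pts[0])
        assert np.allclose(base.normal, cyc.normal, atol=1e-12)
        assert abs(cyc.signed_distance(pts[0])) < 1e-9
        swapped = plane_from_points(pts[1], pts[0], pts[2])
        assert np.allclose(base.normal, -swapped.normal, atol=1e-12)

    def test_members_lie_on_plane(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(3, 3)) * 50
            pl = plane_from_points(*pts)
            scale = max(np.linalg.norm(pts[i] - pts[j])
                        for i in range(3) for j in range(3))
            assert np.all(np.abs(pl.signed_distance(pts)) < 1e-9 * scale)


def sphere_points(center, radius, n, rng, noise=0.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = center + radius * v
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestFitSphere:
    def test_exact_recovery(self, rng):
        pts = sphere_points(np.array([1.0, 2.0, 3.0]), 12.0, 100, rng)
        s = fit_sphere(pts)
        assert np.allclose(s.center, [1, 2, 3], atol=1e-9)
        assert abs(s.radius - 12.0) < 1e-9
        assert s.rms_residual < 1e-9

    def test_noisy_fit_matches_multistart_oracle(self):
        rng = np.random.default_rng(7)
        pts = sphere_points(np.array([1.0, 2.0, 3.0]), 12.0, 2000, rng, noise=0.2)
        s = fit_sphere(pts)

        # oracle: geometric least squares from several independent starts
        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        best = None
        for start in ([0, 0, 0, 5], [2, 3, 4, 20], [1, 2, 3, 12], [-5, 5, 0, 8]):
            r = least_squares(resid, np.array(start, float), method="lm")
            if best is None or r.cost < best.cost:
                best = r
        assert np.linalg.norm(s.center - best.x[:3]) < 0.05
        assert abs(s.radius - best.x[3]) < 0.05
        # and both near truth
        assert np.linalg.norm(s.center - [1, 2, 3]) < 0.05

    def test_too_few_or_coplanar(self, rng):
        with pytest.raises(DegenerateInputError):
            fit_sphere(rng.normal(size=(3, 3)))
        flat = rng.normal(size=(50, 3))
        flat[:, 2] = 4.0
        with pytest.raises(DegenerateInputError):
            fit_sphere(flat)


def cylinder_points(radius, length, n, rng):
    t = rng.uniform(0, length, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), t])


class TestFitAxis:
    def test_axis_aligned_cylinder(self, rng):
        pts = cylinder_points(8.0, 60.0, 500, rng)
        line = fit_axis(pts)
        assert abs(abs(line.direction @ [0, 0, 1]) - 1) < 1e-9

    def test_rotated_cylinder_direction(self, rng):
        pts = cylinder_points(8.0, 60.0, 800, rng)
        for seed in (1, 2, 3):
            R = Rotation.random(random_state=seed).as_matrix()
            line = fit_axis(pts @ R.T)
            want = R @ np.array([0, 0, 1.0])
            ang = np.degrees(np.arccos(np.clip(abs(line.direction @ want), -1, 1)))
            assert ang < 0.1

    def test_noiseless_direction_error_below_microradian(self, rng):
        pts = cylinder_points(5.0, 80.0, 2000, rng)
        line = fit_axis(pts)
        err = np.arccos(np.clip(abs(line.direction @ [0, 0, 1]), -1, 1))
        assert err < 1e-6

    def test_isotropic_cloud_rejected(self, rng):
        pts = sphere_points(np.zeros(3), 10.0, 300, rng)
        with pytest.raises(DegenerateInputError):
            fit_axis(pts)

    def test_proximal_hint_controls_sign(self, rng):
        pts = cylinder_points(8.0, 60.0, 500, rng)
        up = fit_axis(pts, proximal_hint=[0, 0, 1])
        down = fit_axis(pts, proximal_hint=[0, 0, -1])
        assert up.direction[2] > 0 > down.direction[2]


class TestClosestApproach:
    def test_intersecting_axes(self):
        a = Line([0, 0, 0], [1, 0, 0])
        b = Line([0, 0, 0], [0, 1, 0])
        pa, pb, d = closest_approach(a, b)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(pa, [0, 0, 0]) and np.allclose(pb, [0, 0, 0])

    def test_skew_unit_offset(self):
        a = Line([0, 0, 0], [1, 0, 0])
        b = Line([0, 0, 1], [0, 1, 0])
        pa, pb, d = closest_approach(a, b)
        assert d == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pa, [0, 0, 0], atol=1e-12)
        assert np.allclose(pb, [0, 0, 1], atol=1e-12)

    def test_parallel_lines_error(self):
        with pytest.raises(ParallelLinesError):
            closest_approach(Line([0, 0, 0], [1, 0, 0]), Line([0, 1, 0], [1, 0, 0]))

    def test_random_skew_matches_grid_search(self):
        rng = np.random.default_rng(3)
        a = Line(rng.normal(size=3) * 10, rng.normal(size=3))
        b = Line(rng.normal(size=3) * 10, rng.normal(size=3))
        _, _, d = closest_approach(a, b)
        # dense two-parameter oracle, refined around the coarse optimum
        t = np.linspace(-100, 100, 2001)
        pa = a.point + t[:, None] * a.direction
        pb = b.point + t[:, None] * b.direction
        d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        f = minimize(
            lambda x: np.sum((a.point + x[0] * a.direction
                              - b.point - x[1] * b.direction) ** 2),
            x0=[t[i], t[j]], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14})
        assert abs(d - np.sqrt(f.fun)) < 1e-6

    def test_symmetry(self, rng):
        a = Line(rng.normal(size=3), rng.normal(size=3))
        b = Line(rng.normal(size=3), rng.normal(size=3))
        pa, pb, d = closest_approach(a, b)
        qb, qa, d2 = closest_approach(b, a)
        assert d == pytest.approx(d2, abs=1e-12)
        assert np.allclose(pa, qa) and np.allclose(pb, qb)


class TestProjectedAngle:
    def test_signed_quarter_turn(self):
        assert projected_angle([1, 0, 0], [0, 1, 0], [0, 0, 1]) == pytest.approx(-90.0)
        assert projected_angle([0, 1, 0], [1, 0, 0], [0, 0, 1]) == pytest.approx(90.0)

    def test_identity_is_zero(self, rng):
        v = rng.normal(size=3)
        assert projected_angle(v, v, [0, 0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_matches_atan2_hand_computation(self):
        rng = np.random.default_rng(11)
        n = np.array([0.0, 0.0, 1.0])
        for _ in range(50):
            v, ref = rng.normal(size=3), rng.normal(size=3)
            got = projected_angle(v, ref, n)
            want = np.degrees(np.arctan2(v[1], v[0]) - np.arctan2(ref[1], ref[0]))
            want = (want + 180.0) % 360.0 - 180.0
            if want == -180.0:
                want = 180.0
            assert got == pytest.approx(want, abs=1e-9)

    def test_antisymmetry(self, rng):
        v, ref, n = rng.normal(size=3), rng.normal(size=3), np.array([0, 0, 1.0])
        assert projected_angle(v, ref, n) == pytest.approx(
            -projected_angle(ref, v, n), abs=1e-9)

    def test_undefined_projection(self):
        with pytest.raises(DegenerateInputError):
            projected_angle([0, 0, 2], [1, 0, 0], [0, 0, 1])


def test_generator_cut_plane_matches_plane_fit(default_femur):
    """Plane through three generated physeal landmarks reproduces the
    generator's stored cut-plane normal."""
    _, lm, gt = default_femur
    pl = plane_from_points(lm.craniomedial, lm.caudomedial, lm.craniolateral)
    n = pl.normal if pl.normal @ gt.chevron_plane_a.normal > 0 else -pl.normal
    assert np.allclose(n, gt.chevron_plane_a.normal, atol=1e-9)
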