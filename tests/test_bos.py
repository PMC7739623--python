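"""Functional base-of-support geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon

from stsbalance.bos import (
    BosPolygon,
    BosTemplate,
    FootCopProfile,
    build_template,
    calibrate_foot_frame,
    foot_dimensions,
    foot_frame,
    foot_is_flat,
    scale_template,
    signed_distance,
    whole_body_bos,
)

CANONICAL = {
    "FAL": np.array([-0.045, 0.0, 0.06]),
    "TAM": np.array([0.045, 0.0, 0.06]),
    "FM1": np.array([0.035, 0.155, 0.02]),
    "FM2": np.array([0.005, 0.19, 0.02]),
    "FM5": np.array([-0.055, 0.13, 0.02]),
    "FCC": np.array([-0.002, -0.06, 0.03]),
}


class TestFootFrame:
    def test_canonical_flat_foot(self):
        mk = {
            "FAL": [-0.05, 0, 0], "TAM": [0.05, 0, 0],
            "FM1": [0.04, 0.16, 0], "FM5": [-0.04, 0.16, 0],
            "FM2": [0.0, 0.19, 0], "FCC": [0.0, -0.06, 0],
        }
        fr = foot_frame(mk)
        np.testing.assert_allclose(fr.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.y, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.x, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.z, [0, 0, 1], atol=1e-12)

    def test_rotation_equivariance(self):
        R = Rotation.from_euler("z", 0.7).as_matrix()
        fr0 = foot_frame(CANONICAL)
        fr1 = foot_frame({k: R @ v for k, v in CANONICAL.items()})
        np.testing.assert_allclose(fr1.x, R @ fr0.x, atol=1e-12)
        np.testing.assert_allclose(fr1.y, R @ fr0.y, atol=1e-12)
        np.testing.assert_allclose(fr1.z, R @ fr0.z, atol=1e-12)

    def test_coincident_ankle_markers_error(self):
        mk = dict(CANONICAL)
        mk["TAM"] = mk["FAL"]
        with pytest.raises(ValueError):
            foot_frame(mk)

    def test_calibrated_frame_grounded_upright(self):
        fr = calibrate_foot_frame(foot_frame(CANONICAL))
        assert fr.origin[2] == 0.0
        np.testing.assert_allclose(fr.z, [0, 0, 1])
        assert abs(fr.y[2]) < 1e-12


class TestFootDimensions:
    def test_constructed_dimensions(self):
        mk = {
            "FAL": [-0.045, 0, 0], "TAM": [0.045, 0, 0],
            "FM1": [0.045, 0.16, 0], "FM5": [-0.045, 0.16, 0],
            "FM2": [0.0, 0.19, 0], "FCC": [0.0, -0.06, 0],
        }
        w, ell = foot_dimensions(mk)
        assert w == pytest.approx(0.09, abs=1e-12)
        assert ell == pytest.approx(0.25, abs=1e-12)

    def test_rigid_motion_invariance(self):
        R = Rotation.from_euler("zyx", [0.3, 0.1, -0.2]).as_matrix()
        d = np.array([1.0, -2.0, 0.5])
        w0, l0 = foot_dimensions(CANONICAL)
        w1, l1 = foot_dimensions({k: R @ v + d for k, v in CANONICAL.items()})
        assert w1 == pytest.approx(w0, abs=1e-12)
        assert l1 == pytest.approx(l0, abs=1e-12)

    def test_toe_behind_heel_error(self):
        mk = dict(CANONICAL)
        mk["FM2"], mk["FCC"] = mk["FCC"], mk["FM2"]
        with pytest.raises(ValueError):
            foot_dimensions(mk)


class TestFootIsFlat:
    W, L = 0.09, 0.25

    def test_identity_is_flat(self):
        assert foot_is_flat(np.eye(3), self.W, self.L)

    def test_just_over_allowance_not_flat(self):
        psi = np.arcsin(0.016 / self.W)
        R = Rotation.from_euler("X", psi).as_matrix()
        assert not foot_is_flat(R, self.W, self.L)

    def test_boundary_is_inclusive(self):
        psi = np.arcsin(0.015 / self.W)
        R = Rotation.from_euler("X", psi).as_matrix()
        assert foot_is_flat(R, self.W, self.L)


def square_profile(half, n=200, w=0.09, ell=0.25, side="left", center=(0.0, 0.0)):
    """Dense COP samples on a square boundary+interior, in metres."""
    rng = np.random.default_rng(0)
    t = np.linspace(0, 1, n // 4, endpoint=False)
    boundary = np.vstack([
        np.column_stack([-half + 2 * half * t, np.full_like(t, -half)]),
        np.column_stack([np.full_like(t, half), -half + 2 * half * t]),
        np.column_stack([half - 2 * half * t, np.full_like(t, half)]),
        np.column_stack([np.full_like(t, -half), half - 2 * half * t]),
    ]) + np.asarray(center)
    pts = boundary * np.array([w, ell])  # normalized coords -> metres
    return FootCopProfile(cop_local=pts, force=np.full(len(pts), 600.0),
                          flat=np.ones(len(pts), bool), width=w, length=ell,
                          side=side)


class TestBuildTemplate:
    def test_single_square_recovered(self):
        prof = square_profile(0.4, center=(-0.15, 0.3))
        tpl = build_template([prof], body_weight=700.0, center=(-0.15, 0.3))
        area = Polygon(tpl.vertices).area
        assert area == pytest.approx(0.8**2, rel=0.01)

    def test_concentric_squares_ray_average(self):
        a, b = 0.25, 0.45
        c = (-0.15, 0.3)
        profs = [square_profile(a, center=c), square_profile(b, center=c)]
        tpl = build_template(profs, body_weight=700.0, center=c, n_rays=360)
        # dense ray-sampling oracle: mean of the two squares' radii per angle
        ang = np.arctan2(tpl.vertices[:, 1] - c[1], tpl.vertices[:, 0] - c[0])
        r_tpl = np.hypot(*(tpl.vertices - c).T)
        for theta, r in zip(ang, r_tpl):
            d = max(abs(np.cos(theta)), abs(np.sin(theta)))
            r_oracle = 0.5 * (a / d + b / d)
            assert r <= r_oracle + 1e-9  # convexification can only trim

    def test_mirrored_pair_symmetric(self):
        # an anatomically mirrored pair yields identical local coordinates;
        # the builder's right-foot reflection plus an on-axis averaging
        # center makes the template symmetric by construction
        left = square_profile(0.4, center=(0.05, 0.3), side="left")
        right = square_profile(0.4, center=(0.05, 0.3), side="right")
        tpl = build_template([left, right], body_weight=700.0, center=(0.0, 0.3))
        mirrored = tpl.vertices * np.array([-1.0, 1.0])
        p1, p2 = Polygon(tpl.vertices), Polygon(mirrored)
        assert p1.symmetric_difference(p2).area < 1e-12

    def test_all_below_half_weight_errors(self):
        prof = square_profile(0.4, center=(-0.15, 0.3))
        prof.force[:] = 100.0
        with pytest.raises(ValueError):
            build_template([prof], body_weight=700.0)

    def test_tilted_only_errors(self):
        prof = square_profile(0.4, center=(-0.15, 0.3))
        prof.flat[:] = False
        with pytest.raises(ValueError):
            build_template([prof], body_weight=700.0)


def unit_square_template():
    v = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return BosTemplate(vertices=v, center=np.array([0.5, 0.5]))


def identity_frame(side="left"):
    from stsbalance.bos import FootFrame
    return FootFrame(origin=np.zeros(3), x=np.array([1.0, 0, 0]),
                     y=np.array([0.0, 1, 0]), z=np.array([0.0, 0, 1]), side=side)


class TestScaleTemplate:
    def test_unit_identity(self):
        poly = scale_template(unit_square_template(), 1.0, 1.0, identity_frame())
        assert Polygon(poly.vertices).equals(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))

    def test_doubling_width_scales_x_only(self):
        poly = scale_template(unit_square_template(), 2.0, 1.0, identity_frame())
        xs, ys = poly.vertices[:, 0], poly.vertices[:, 1]
        assert xs.max() == pytest.approx(2.0) and ys.max() == pytest.approx(1.0)

    def test_translation_equivariance(self):
        fr = identity_frame()
        fr.origin = np.array([0.3, -0.2, 0.0])
        a = scale_template(unit_square_template(), 1.0, 1.0, identity_frame())
        b = scale_template(unit_square_template(), 1.0, 1.0, fr)
        np.testing.assert_allclose(
            sorted(map(tuple, b.vertices)),
            sorted(map(tuple, a.vertices + np.array([0.3, -0.2]))), atol=1e-12)

    def test_scale_unscale_roundtrip(self):
        tpl = unit_square_template()
        poly = scale_template(tpl, 0.09, 0.25, identity_frame())
        back = poly.vertices / np.array([0.09, 0.25])
        assert Polygon(back).symmetric_difference(Polygon(tpl.vertices)).area < 1e-12


class TestWholeBodyBos:
    def test_identical_polygons(self):
        sq = BosPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        hull = whole_body_bos(sq, sq)
        assert Polygon(hull.vertices).equals(sq.shapely)

    def test_two_squares_hull_is_rectangle(self):
        a = BosPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        b = BosPolygon(np.array([[2, 0], [3, 0], [3, 1], [2, 1]], float))
        hull = whole_body_bos(a, b)
        assert Polygon(hull.vertices).equals(Polygon([(0, 0), (3, 0), (3, 1), (0, 1)]))

    def test_hull_contains_all_vertices(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = BosPolygon(_rand_convex(rng))
            b = BosPolygon(_rand_convex(rng) + rng.normal(size=2))
            hull = whole_body_bos(a, b).shapely.buffer(1e-9)
            for v in np.vstack([a.vertices, b.vertices]):
                assert hull.covers(Polygon([v, v + 1e-12, v + [0, 1e-12]]))


def _rand_convex(rng, n=8):
    pts = rng.normal(size=(n, 2))
    from stsbalance.bos import _hull_vertices
    return _hull_vertices(pts)


def brute_signed_distance(p, verts):
    """Edge-enumeration + winding oracle."""
    n = len(verts)
    dmin = np.inf
    inside = True
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        e = b - a
        t = np.clip(np.dot(p - a, e) / np.dot(e, e), 0.0, 1.0)
        dmin = min(dmin, np.linalg.norm(p - (a + t * e)))
        r = p - a
        if e[0] * r[1] - e[1] * r[0] < 0:  # CCW polygon: outside this edge
            inside = False
    return dmin if inside else -dmin


class TestSignedDistance:
    unit = BosPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))

    def test_center_of_unit_square(self):
        assert signed_distance(np.array([0.5, 0.5]), self.unit) == pytest.approx(0.5)

    def test_outside_unit_square(self):
        assert signed_distance(np.array([1.5, 0.5]), self.unit) == pytest.approx(-0.5)

    def test_boundary_is_zero(self):
        assert signed_distance(np.array([1.0, 0.5]), self.unit) == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            verts = _rand_convex(rng)
            poly = BosPolygon(verts)
            pts = rng.normal(scale=2.0, size=(50, 2))
            d = signed_distance(pts, poly)
            for p, di in zip(pts, d):
                assert di == pytest.approx(brute_signed_distance(p, verts), abs=1e-12)

    def test_lipschitz_across_boundary(self):
        rng = np.random.default_rng(5)
        poly = BosPolygon(_rand_convex(rng))
        p = rng.normal(size=2)
        for _ in range(50):
            q = p + rng.normal(scale=0.05, size=2)
            dp, dq = signed_distance(p, poly), signed_distance(q, poly)
            assert abs(dp - dq) <= np.linalg.norm(p - q) + 1e-12
            p = q

    def test_nan_points_propagate(self):
        d = signed_distance(np.array([[np.nan, 0.2], [0.5, 0.5]]), self.unit)
        assert np.isnan(d[0]) and d[1] == pytest.approx(0.5)
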