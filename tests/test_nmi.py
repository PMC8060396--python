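"""Signed margin distances and the Niche Margin Index."""

import numpy as np
import pytest
import shapely
from shapely.geometry import MultiPolygon, Polygon

from nichemargin import (
    NicheEnvelope,
    ellipsoid_signed_distance,
    max_inner_distance,
    nmi,
    signed_margin_distance,
    signed_margin_distances,
)
from conftest import oracle_signed_distance, random_convex_polygon, regular_polygon_envelope


class TestSignedDistance:
    def test_boundary_vertex_has_zero_distance(self, square_envelope):
        assert signed_margin_distance((0.0, 0.0), square_envelope) == pytest.approx(0.0, abs=1e-12)

    def test_unit_square_interior_and_exterior(self, square_envelope):
        assert signed_margin_distance((0.5, 0.5), square_envelope) == pytest.approx(0.5)
        assert signed_margin_distance((2.0, 0.5), square_envelope) == pytest.approx(-1.0)

    def test_hole_interior_counts_as_outside(self):
        outer = Polygon(
            [(0, 0), (1, 0), (1, 1), (0, 1)],
            holes=[[(0.25, 0.25), (0.75, 0.25), (0.75, 0.75), (0.25, 0.75)]],
        )
        env = NicheEnvelope(method="kde", level=0.95, geometry=MultiPolygon([outer]))
        d = signed_margin_distance((0.5, 0.5), env)
        assert d == pytest.approx(-0.25)

    def test_matches_brute_force_oracle_on_random_convex_polygons(self, rng):
        for _ in range(20):
            ring = random_convex_polygon(rng)
            env = NicheEnvelope(method="mve", level=0.95, geometry=MultiPolygon([Polygon(ring)]))
            pts = rng.uniform(-6, 6, size=(20, 2))
            got = signed_margin_distances(pts, env)
            want = [oracle_signed_distance(p, [ring]) for p in pts]
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_missing_coordinates_flagged(self, square_envelope):
        got = signed_margin_distances(np.array([[np.nan, 0.5], [0.5, 0.5]]), square_envelope)
        assert np.isnan(got[0]) and got[1] == pytest.approx(0.5)


class TestMaxInnerDistance:
    def test_disc_inradius(self, disc_envelope):
        assert max_inner_distance(disc_envelope) == pytest.approx(1.0, rel=0.02)

    def test_square_inradius(self, square_envelope):
        assert max_inner_distance(square_envelope) == pytest.approx(0.5, rel=0.02)

    def test_scaling_doubles_denominator(self, rng):
        ring = random_convex_polygon(rng, scale=2.0)
        env1 = NicheEnvelope(method="mve", level=0.9, geometry=MultiPolygon([Polygon(ring)]))
        env2 = NicheEnvelope(method="mve", level=0.9, geometry=MultiPolygon([Polygon(2 * ring)]))
        assert max_inner_distance(env2) == pytest.approx(2 * max_inner_distance(env1), rel=0.03)

    def test_cached_per_envelope(self, square_envelope):
        a = max_inner_distance(square_envelope)
        assert square_envelope._denominators[10000] == a


class TestNMI:
    def test_disc_radial_profile(self, disc_envelope):
        res = nmi(np.array([[0.25, 0.0], [2.0, 0.0]]), disc_envelope)
        assert res[0].nmi == pytest.approx(0.75, abs=0.02)
        assert res[1].nmi == pytest.approx(-1.0, abs=0.02)
        assert res[0].inside and not res[1].inside

    def test_on_margin_is_zero(self, square_envelope):
        res = nmi(np.array([[0.0, 0.5]]), square_envelope)
        assert res[0].nmi == pytest.approx(0.0, abs=1e-12)

    def test_deepest_lattice_point_scores_one(self, disc_envelope):
        from nichemargin.nmi import _interior_lattice

        lattice = _interior_lattice(disc_envelope, 10000)
        d = shapely.distance(
            shapely.points(lattice[:, 0], lattice[:, 1]), disc_envelope.boundary
        )
        best = lattice[np.argmax(d)]
        res = nmi(best[None, :], disc_envelope)
        assert res[0].nmi == pytest.approx(1.0, abs=1e-9)

    def test_nmi_never_exceeds_one_beyond_lattice_tolerance(self, rng, disc_envelope):
        pts = rng.uniform(-1, 1, size=(200, 2))
        res = nmi(pts, disc_envelope)
        assert max(r.nmi for r in res) <= 1.0 + 0.02

    def test_similarity_invariance(self, rng):
        ring = random_convex_polygon(rng)
        pts = rng.uniform(-4, 4, size=(30, 2))
        theta, s, t = 1.1, 3.0, np.array([5.0, -2.0])
        R = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        env_a = NicheEnvelope(method="mve", level=0.9, geometry=MultiPolygon([Polygon(ring)]))
        env_b = NicheEnvelope(
            method="mve", level=0.9, geometry=MultiPolygon([Polygon(ring @ R.T + t)])
        )
        # distances transform exactly (scale by s); NMI is invariant up to
        # the lattice tolerance of the standardization denominator
        da = signed_margin_distances(pts, env_a)
        db = signed_margin_distances(pts @ R.T + t, env_b)
        np.testing.assert_allclose(db, s * da, atol=1e-6)
        a = [r.nmi for r in nmi(pts, env_a)]
        b = [r.nmi for r in nmi(pts @ R.T + t, env_b)]
        np.testing.assert_allclose(a, b, rtol=0.02, atol=0.02)

    def test_monotone_along_outward_ray(self, disc_envelope):
        radii = np.linspace(0, 3, 40)
        pts = np.column_stack([radii, np.zeros_like(radii)])
        vals = np.array([r.nmi for r in nmi(pts, disc_envelope)])
        assert np.all(np.diff(vals) <= 1e-9)

    def test_scaled_copies_give_same_relative_nmi(self):
        small = regular_polygon_envelope(radius=1.0)
        large = regular_polygon_envelope(radius=7.0)
        a = nmi(np.array([[0.5, 0.0]]), small)[0].nmi
        b = nmi(np.array([[3.5, 0.0]]), large)[0].nmi
        assert a == pytest.approx(b, abs=1e-3)

    def test_missing_coordinates_propagate(self, square_envelope):
        res = nmi(np.array([[np.nan, np.nan]]), square_envelope)
        assert res[0].missing and np.isnan(res[0].nmi) and res[0].inside is None


class TestEllipsoidDistance:
    def test_sphere_reduces_to_radius_arithmetic(self):
        A = np.eye(3) / 4.0  # sphere of radius 2
        assert ellipsoid_signed_distance([1, 0, 0], np.zeros(3), A) == pytest.approx(1.0)
        assert ellipsoid_signed_distance([3, 0, 0], np.zeros(3), A) == pytest.approx(-1.0)
        assert ellipsoid_signed_distance([0, 0, 0], np.zeros(3), A) == pytest.approx(2.0)

    def test_matches_polygon_distance_in_two_dimensions(self, rng):
        from nichemargin.envelope import _ellipse_polygon

        A = np.diag([1 / 4.0, 1.0])  # ellipse with semi-axes (2, 1)
        env = NicheEnvelope(
            method="mve", level=0.95,
            geometry=MultiPolygon([_ellipse_polygon(np.zeros(2), A, 4096)]),
        )
        for p in rng.uniform(-3, 3, size=(25, 2)):
            want = signed_margin_distance(p, env)
            got = ellipsoid_signed_distance(p, np.zeros(2), A)
            assert got == pytest.approx(want, abs=5e-4)
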