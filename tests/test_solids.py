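"""Geometry primitives: stadium construction, closed-form mass properties
versus a numerical-integration oracle, and frame transport."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsip.solids import (
    FrameTransform,
    GeometryError,
    RigidBodyProperties,
    Semiellipsoid,
    Stadium,
    StadiumSolid,
    semiellipsoid_properties,
    stadium_from_attributes,
    stadium_solid_properties,
    transport_properties,
)
from bsip.synthetic import numeric_mass_properties_oracle

sizes = st.floats(min_value=1e-3, max_value=1.0, allow_nan=False)


def tensor_invariants(inertia, scale=None):
    """Symmetry, positive semi-definiteness, triangle inequalities."""
    inertia = np.asarray(inertia)
    scale = scale or max(np.abs(inertia).max(), 1e-30)
    assert np.allclose(inertia, inertia.T, atol=1e-12 * scale)
    lams = np.sort(np.linalg.eigvalsh(inertia))
    assert lams[0] >= -1e-12 * scale
    assert lams[0] + lams[1] >= lams[2] - 1e-9 * scale


class TestStadiumFromAttributes:
    @pytest.mark.parametrize(
        "kwargs, r, t",
        [
            # ratio exactly pi: the stadium is a circle
            (dict(perimeter=2 * math.pi, width=2.0), 1.0, 0.0),
            # invert p = 4t + 2*pi*r, w = 2(t+r)
            (dict(perimeter=10.0, width=4.0),
             (10.0 - 8.0) / (2 * math.pi - 4), 2.0 - (10.0 - 8.0) / (2 * math.pi - 4)),
            (dict(width=4.0, depth=2.0), 1.0, 1.0),
            # p/w = 1.75 < 2: circle recovered from the perimeter
            (dict(perimeter=7.0, width=4.0), 7.0 / (2 * math.pi), 0.0),
            (dict(perimeter=2 * math.pi), 1.0, 0.0),
            (dict(radius=0.3, thickness=0.1), 0.3, 0.1),
        ],
    )
    def test_examples(self, kwargs, r, t):
        stadium = stadium_from_attributes(**kwargs)
        assert stadium.radius == pytest.approx(r, rel=1e-12)
        assert stadium.thickness == pytest.approx(t, abs=1e-12)

    def test_forward_relations_reproduce_inputs(self):
        stadium = stadium_from_attributes(perimeter=10.0, width=4.0)
        assert stadium.perimeter == pytest.approx(10.0, rel=1e-12)
        assert stadium.width == pytest.approx(4.0, rel=1e-12)

    def test_fallback_emits_message(self):
        messages = []
        stadium = stadium_from_attributes(
            perimeter=7.0, width=4.0, on_fallback=messages.append
        )
        assert stadium.is_circle
        assert len(messages) == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(perimeter=-1.0, width=2.0),
            dict(width=2.0, depth=3.0),          # depth exceeds width
            dict(radius=0.1, width=2.0),         # unsupported pair
            dict(perimeter=1.0, width=2.0, depth=3.0),
        ],
    )
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(GeometryError):
            stadium_from_attributes(**kwargs)

    @given(r=sizes, t=sizes)
    @settings(derandomize=True)
    def test_perimeter_width_ratio_bounds(self, r, t):
        stadium = Stadium(r, t)
        assert 2.0 < stadium.perimeter / stadium.width < math.pi


class TestStadiumSolidClosedForms:
    def test_cylinder(self):
        solid = StadiumSolid(Stadium(1.0, 0.0), Stadium(1.0, 0.0), 2.0, 1.0)
        p = stadium_solid_properties(solid)
        m = 2.0 * math.pi
        assert p.mass == pytest.approx(m, rel=1e-12)
        assert p.com[2] == pytest.approx(1.0, rel=1e-12)
        assert p.inertia[2, 2] == pytest.approx(m / 2.0, rel=1e-12)
        # about the bottom-face centre: m (r^2/4 + h^2/3)
        assert p.inertia[0, 0] == pytest.approx(m * (0.25 + 4.0 / 3.0), rel=1e-12)

    def test_frustum(self):
        solid = StadiumSolid(Stadium(1.0, 0.0), Stadium(0.5, 0.0), 1.0, 1.0)
        p = stadium_solid_properties(solid)
        assert p.mass == pytest.approx(math.pi / 3.0 * 1.75, rel=1e-12)

    def test_errors(self):
        with pytest.raises(GeometryError):
            StadiumSolid(Stadium(1.0, 0.1), Stadium(1.0, 0.1), -1.0, 1.0)
        with pytest.raises(GeometryError):
            StadiumSolid(Stadium(1.0, 0.1), Stadium(1.0, 0.1), 1.0, 0.0)
        with pytest.raises(GeometryError):
            StadiumSolid(
                Stadium(1.0, 0.1, "mediolateral"),
                Stadium(1.0, 0.1, "anteroposterior"),
                1.0, 1.0,
            )

    @given(r0=sizes, t0=sizes, r1=sizes, t1=sizes, h=sizes,
           rho=st.floats(min_value=100.0, max_value=2000.0))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_matches_numerical_oracle(self, r0, t0, r1, t1, h, rho):
        solid = StadiumSolid(Stadium(r0, t0), Stadium(r1, t1), h, rho)
        analytic = stadium_solid_properties(solid)
        oracle = numeric_mass_properties_oracle(solid, resolution=48)
        scale = np.abs(oracle.inertia).max()
        assert analytic.mass == pytest.approx(oracle.mass, rel=1e-10)
        assert analytic.com[2] == pytest.approx(oracle.com[2], rel=1e-10)
        assert np.abs(analytic.inertia - oracle.inertia).max() <= 1e-8 * scale

    @given(r0=sizes, t0=sizes, r1=sizes, t1=sizes, h=sizes)
    @settings(derandomize=True, max_examples=40)
    def test_com_on_axis_and_tensor_invariants(self, r0, t0, r1, t1, h):
        p = stadium_solid_properties(
            StadiumSolid(Stadium(r0, t0), Stadium(r1, t1), h, 1000.0)
        )
        assert abs(p.com[0]) < 1e-14 and abs(p.com[1]) < 1e-14
        assert 0.0 < p.com[2] < h
        tensor_invariants(p.about_com().inertia)

    @given(r0=sizes, r1=sizes, t1=sizes, h=sizes)
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_degenerate_bottom_agrees_with_tiny_thickness(self, r0, r1, t1, h):
        """A bottom circle handled by the swapped-stadia path must agree
        with the generic path evaluated at a vanishing thickness."""
        exact = stadium_solid_properties(
            StadiumSolid(Stadium(r0, 0.0), Stadium(r1, t1), h, 1000.0)
        )
        eps = stadium_solid_properties(
            StadiumSolid(Stadium(r0, 1e-9), Stadium(r1, t1), h, 1000.0)
        )
        assert exact.mass == pytest.approx(eps.mass, rel=1e-5)
        assert exact.com[2] == pytest.approx(eps.com[2], rel=1e-5)
        scale = np.abs(exact.inertia).max()
        assert np.abs(exact.inertia - eps.inertia).max() <= 1e-5 * scale

    def test_both_circles_uses_frustum_continuously(self):
        near = stadium_solid_properties(
            StadiumSolid(Stadium(0.2, 1e-9), Stadium(0.1, 1e-9), 0.5, 1000.0)
        )
        cone = stadium_solid_properties(
            StadiumSolid(Stadium(0.2, 0.0), Stadium(0.1, 0.0), 0.5, 1000.0)
        )
        assert cone.mass == pytest.approx(near.mass, rel=1e-6)
        assert np.allclose(cone.inertia, near.inertia, rtol=1e-5)


class TestSemiellipsoid:
    def test_hemisphere(self):
        p = semiellipsoid_properties(Semiellipsoid(1.0, 1.0, 1.0, 1.0))
        m = 2.0 * math.pi / 3.0
        assert p.mass == pytest.approx(m, rel=1e-12)
        assert p.com[2] == pytest.approx(0.375, rel=1e-12)
        assert p.inertia[2, 2] == pytest.approx(0.4 * m, rel=1e-12)

    def test_mass_and_com_linear_in_height(self):
        p1 = semiellipsoid_properties(Semiellipsoid(0.1, 0.2, 0.3, 800.0))
        p2 = semiellipsoid_properties(Semiellipsoid(0.1, 0.2, 0.6, 800.0))
        assert p2.mass == pytest.approx(2.0 * p1.mass, rel=1e-12)
        assert p2.com[2] == pytest.approx(2.0 * p1.com[2], rel=1e-12)

    def test_matches_numerical_oracle(self):
        solid = Semiellipsoid(0.07, 0.09, 0.11, 1050.0)
        analytic = semiellipsoid_properties(solid)
        oracle = numeric_mass_properties_oracle(solid, resolution=64)
        assert analytic.mass == pytest.approx(oracle.mass, rel=1e-8)
        scale = np.abs(oracle.inertia).max()
        assert np.abs(analytic.inertia - oracle.inertia).max() <= 1e-8 * scale

    def test_errors(self):
        with pytest.raises(GeometryError):
            Semiellipsoid(0.0, 0.1, 0.1, 1.0)


class TestTransport:
    def test_identity(self):
        p = RigidBodyProperties(2.0, [0.1, 0.2, 0.3], np.diag([1.0, 2.0, 3.0]))
        q = transport_properties(p, FrameTransform())
        assert np.allclose(q.com, p.com) and np.allclose(q.inertia, p.inertia)
        assert q.mass == p.mass

    def test_parallel_axis(self):
        # tensor about the COM; move the reference point 1 m along -z
        p = RigidBodyProperties(2.0, [0.0, 0.0, 0.0], np.eye(3))
        q = transport_properties(p, FrameTransform(origin=[0.0, 0.0, 1.0]))
        assert np.allclose(q.inertia, np.diag([3.0, 3.0, 1.0]))

    def test_rotation_preserves_spectrum(self):
        rng = np.random.default_rng(7)
        inertia = np.diag([1.0, 2.0, 3.0])
        p = RigidBodyProperties(1.5, [0.1, -0.2, 0.3], inertia)
        q_mat, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q_mat) < 0:
            q_mat[:, 0] *= -1
        out = transport_properties(p, FrameTransform(q_mat, np.zeros(3)))
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(out.about_com().inertia)),
            np.sort(np.linalg.eigvalsh(p.about_com().inertia)),
            atol=1e-12,
        )

    def test_round_trip(self):
        p = RigidBodyProperties(2.5, [0.1, 0.2, 0.3], np.diag([4.0, 5.0, 6.0]))
        rot = FrameTransform(
            np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
            [0.5, -0.5, 1.0],
        )
        inverse = FrameTransform(rot.rotation.T, -rot.rotation.T @ rot.origin)
        q = transport_properties(transport_properties(p, rot), inverse)
        assert np.allclose(q.com, p.com, atol=1e-12)
        assert np.allclose(q.inertia, p.inertia, atol=1e-12)

    def test_rejects_non_orthonormal(self):
        with pytest.raises(GeometryError):
            FrameTransform(np.diag([1.0, 2.0, 1.0]))
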