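"""Primitive solids and rigid-body mass properties.

The body is built from two solid primitives:

* a *stadium solid*: the loft between two parallel stadium cross sections
  (a stadium is a rectangle capped by two semicircles; with zero rectangle
  thickness it degenerates to a circle), with the radius and thickness
  varying linearly along the longitudinal axis;
* a *semi-ellipsoid*: half of a solid ellipsoid, flat face down, used for
  the cranium.

Mass, centre of mass, and the inertia tensor of both primitives are exact
closed forms obtained by polynomial integration of the cross section's
area and second moments along the longitudinal axis.  The stadium-solid
forms are written in the parameterisation

    r(z) = r0 * (1 + a*z/h),   t(z) = t0 * (1 + b*z/h),

with ``a = r1/r0 - 1`` and ``b = t1/t0 - 1``.  Forming ``b`` divides by
``t0``, so a solid whose *bottom* stadium is a circle is evaluated with its
stadia swapped (the solid upside down) and the result transported back; a
solid bounded by two circles is a conical frustum with its own closed
forms.  No small-thickness approximation is used anywhere.

Rigid-body properties are carried by :class:`RigidBodyProperties` (mass,
centre of mass, 3x3 inertia tensor about a stated reference point) and
moved between frames with :func:`transport_properties`, which applies the
rotation and the generalised parallel axis theorem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MEDIOLATERAL",
    "ANTEROPOSTERIOR",
    "Stadium",
    "StadiumSolid",
    "Semiellipsoid",
    "RigidBodyProperties",
    "FrameTransform",
    "stadium_from_attributes",
    "stadium_solid_properties",
    "semiellipsoid_properties",
    "transport_properties",
]

#: Orientation flags: the stadium's width axis is mediolateral (the default
#: for almost every level) or anteroposterior (the heels).
MEDIOLATERAL = "mediolateral"
ANTEROPOSTERIOR = "anteroposterior"


class GeometryError(ValueError):
    """Invalid geometric input (non-positive size, impossible stadium...)."""


@dataclass(frozen=True)
class Stadium:
    """A stadium cross section: a ``2t x 2r`` rectangle capped by two
    semicircles of radius ``r``.

    The width axis (local x unless ``orientation`` is anteroposterior)
    has total extent ``w = 2(t + r)``; the depth axis ``d = 2r``.  With
    ``t == 0`` the stadium is a circle.
    """

    radius: float
    thickness: float
    orientation: str = MEDIOLATERAL
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius < 0 or self.thickness < 0:
            raise GeometryError(
                f"stadium {self.label!r}: radius and thickness must be "
                f"non-negative (r={self.radius}, t={self.thickness})"
            )
        if self.orientation not in (MEDIOLATERAL, ANTEROPOSTERIOR):
            raise GeometryError(f"unknown stadium orientation {self.orientation!r}")

    @property
    def width(self) -> float:
        return 2.0 * (self.thickness + self.radius)

    @property
    def depth(self) -> float:
        return 2.0 * self.radius

    @property
    def perimeter(self) -> float:
        return 4.0 * self.thickness + 2.0 * math.pi * self.radius

    @property
    def area(self) -> float:
        return 4.0 * self.radius * self.thickness + math.pi * self.radius**2

    @property
    def is_circle(self) -> bool:
        return self.thickness == 0.0


def stadium_from_attributes(
    *,
    perimeter: float | None = None,
    width: float | None = None,
    depth: float | None = None,
    radius: float | None = None,
    thickness: float | None = None,
    orientation: str = MEDIOLATERAL,
    label: str = "",
    on_fallback=None,
) -> Stadium:
    """Build a :class:`Stadium` from two of its attributes.

    Supported combinations: ``perimeter+width``, ``perimeter+depth``,
    ``width+depth``, ``radius+thickness``, and ``perimeter`` alone (a
    circle).  A physical stadium requires ``2 < p/w < pi``; measured pairs
    violating that are downgraded to a circle recovered from the perimeter
    when one was supplied, else from the width.  The boundary ratios are
    degenerate but valid (``p/w == 2`` is a line, ``p/w == pi`` a circle).

    ``on_fallback`` is called with a message when a downgrade happens (the
    measurement modules route this to a warning log).
    """
    given = {
        "perimeter": perimeter,
        "width": width,
        "depth": depth,
        "radius": radius,
        "thickness": thickness,
    }
    names = [k for k, v in given.items() if v is not None]
    for k in names:
        if given[k] < 0 or (given[k] == 0 and k not in ("thickness",)):
            raise GeometryError(f"stadium {label!r}: attribute {k} must be positive")

    def fallback_circle(p=None, w=None, reason=""):
        r = p / (2.0 * math.pi) if p is not None else w / 2.0
        if on_fallback is not None:
            on_fallback(
                f"stadium {label!r}: {reason}; assuming a circle with r={r:.6g}"
            )
        return Stadium(r, 0.0, orientation, label)

    key = frozenset(names)
    if key == {"radius", "thickness"}:
        return Stadium(radius, thickness, orientation, label)
    if key == {"perimeter"}:
        return Stadium(perimeter / (2.0 * math.pi), 0.0, orientation, label)
    if key == {"perimeter", "width"}:
        ratio = perimeter / width
        if ratio <= 2.0 or ratio >= math.pi:
            if ratio == math.pi:
                return Stadium(perimeter / (2.0 * math.pi), 0.0, orientation, label)
            if ratio == 2.0:  # degenerate line segment
                return Stadium(0.0, width / 2.0, orientation, label)
            return fallback_circle(p=perimeter, reason=f"p/w = {ratio:.4g} not in (2, pi)")
        r = (perimeter - 2.0 * width) / (2.0 * math.pi - 4.0)
        return Stadium(r, width / 2.0 - r, orientation, label)
    if key == {"perimeter", "depth"}:
        r = depth / 2.0
        t = (perimeter - math.pi * depth) / 4.0
        if t < 0.0:
            return fallback_circle(p=perimeter, reason=f"p = {perimeter:.4g} < pi*d")
        return Stadium(r, t, orientation, label)
    if key == {"width", "depth"}:
        if depth > width:
            raise GeometryError(
                f"stadium {label!r}: depth {depth} exceeds width {width}"
            )
        r = depth / 2.0
        return Stadium(r, (width - depth) / 2.0, orientation, label)
    raise GeometryError(
        f"stadium {label!r}: unsupported attribute combination {sorted(names)}"
    )


@dataclass(frozen=True)
class StadiumSolid:
    """Loft between two parallel stadia a distance ``height`` apart.

    The cross section at height z interpolates radius and thickness
    linearly between ``bottom`` (z=0) and ``top`` (z=height).  Both stadia
    must share an orientation (a circle is orientation-neutral).
    """

    bottom: Stadium
    top: Stadium
    height: float
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise GeometryError(f"solid {self.label!r}: height must be > 0")
        if self.density <= 0:
            raise GeometryError(f"solid {self.label!r}: density must be > 0")
        if (
            self.bottom.orientation != self.top.orientation
            and not self.bottom.is_circle
            and not self.top.is_circle
        ):
            raise GeometryError(
                f"solid {self.label!r}: bounding stadia have mismatched orientations"
            )

    @property
    def orientation(self) -> str:
        """Orientation of the solid's width axis (circles defer to the
        non-circular bounding stadium)."""
        if self.bottom.is_circle and not self.top.is_circle:
            return self.top.orientation
        return self.bottom.orientation


@dataclass(frozen=True)
class Semiellipsoid:
    """Half-ellipsoid with semi-axes ``a`` (x), ``b`` (y), apex height
    ``c`` (z); flat face in the base plane z=0."""

    a: float
    b: float
    c: float
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0 or self.density <= 0:
            raise GeometryError(
                f"semiellipsoid {self.label!r}: semi-axes and density must be > 0"
            )


@dataclass(frozen=True)
class RigidBodyProperties:
    """Mass, centre of mass, and inertia tensor about a stated reference
    point, expressed in a stated frame.

    ``com`` is the centre-of-mass position relative to the reference
    point; ``inertia`` is the 3x3 symmetric tensor about the reference
    point in the same axes.
    """

    mass: float
    com: np.ndarray
    inertia: np.ndarray
    frame_tag: str = "local"

    def __post_init__(self) -> None:
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float).reshape(3))
        object.__setattr__(
            self, "inertia", np.asarray(self.inertia, dtype=float).reshape(3, 3)
        )
        if self.mass < 0:
            raise GeometryError("mass must be non-negative")

    def about_com(self) -> "RigidBodyProperties":
        """The same body with the reference point moved to its COM."""
        d = self.com
        shift = self.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
        return replace(self, com=np.zeros(3), inertia=self.inertia - shift)


@dataclass(frozen=True)
class FrameTransform:
    """Rigid transform: coordinates map as ``x_new = rotation @ x_old +
    origin``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        o = np.asarray(self.origin, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "origin", o)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or np.linalg.det(R) < 0:
            raise GeometryError("rotation must be proper orthonormal")

    def compose(self, other: "FrameTransform") -> "FrameTransform":
        """self after other: ``x -> self(other(x))``."""
        return FrameTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.origin + self.origin,
        )


def transport_properties(
    props: RigidBodyProperties,
    xf: FrameTransform,
    frame_tag: str | None = None,
) -> RigidBodyProperties:
    """Re-express rigid-body properties under a frame transform.

    The input tensor is about the input reference point; the output tensor
    is about the *new frame's origin* (the image of the old reference
    point is ``xf.origin`` plus rotation of the zero vector, i.e. the old
    point maps to ``xf(0)``), in the rotated axes.  Concretely: rotate the
    tensor (``R I R^T``) and the COM, then shift the reference point from
    ``xf(0)`` back to the origin with the parallel axis theorem applied
    about the COM.
    """
    R = xf.rotation
    m = props.mass
    # rotate about the (image of the) old reference point
    inertia_rot = R @ props.inertia @ R.T
    com_new = R @ props.com + xf.origin
    # move the tensor's reference point from xf(0)=origin_offset to 0
    at_com = inertia_rot - _paxis(m, R @ props.com)
    inertia_new = at_com + _paxis(m, com_new)
    return RigidBodyProperties(
        m, com_new, inertia_new, frame_tag or props.frame_tag
    )


def _paxis(mass: float, d: np.ndarray) -> np.ndarray:
    """Parallel-axis increment for a reference point displaced by -d from
    the COM (tensor about point p with com at p + d)."""
    d = np.asarray(d, dtype=float)
    return mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _poly_integrals(a: float, b: float) -> dict[str, float]:
    """Exact values of F(m,n,k) = int_0^1 (1+a*u)^m (1+b*u)^n u^k du for
    the (m, n, k) combinations the stadium-solid forms need.  Each is the
    term-wise integral of the expanded polynomial."""
    return {
        "F110": 1.0 + (a + b) / 2.0 + a * b / 3.0,
        "F200": 1.0 + a + a * a / 3.0,
        "F111": 0.5 + (a + b) / 3.0 + a * b / 4.0,
        "F201": 0.5 + 2.0 * a / 3.0 + a * a / 4.0,
        "F112": 1.0 / 3.0 + (a + b) / 4.0 + a * b / 5.0,
        "F202": 1.0 / 3.0 + a / 2.0 + a * a / 5.0,
        "F400": 1.0 + 2.0 * a + 2.0 * a * a + a**3 + a**4 / 5.0,
        "F310": (
            1.0 + 1.5 * a + 0.5 * b + a * a + a * b
            + 0.25 * a**3 + 0.75 * a * a * b + a**3 * b / 5.0
        ),
        "F220": (
            1.0 + a + b + (a * a + 4.0 * a * b + b * b) / 3.0
            + (a * a * b + a * b * b) / 2.0 + a * a * b * b / 5.0
        ),
        "F130": (
            1.0 + 1.5 * b + 0.5 * a + b * b + a * b
            + 0.25 * b**3 + 0.75 * b * b * a + b**3 * a / 5.0
        ),
    }


def _generic_stadium_solid(
    r0: float, t0: float, r1: float, t1: float, h: float, rho: float
) -> RigidBodyProperties:
    """Closed forms in the (a, b) taper parameterisation; needs r0, t0 > 0."""
    a = r1 / r0 - 1.0
    b = t1 / t0 - 1.0
    F = _poly_integrals(a, b)
    pi = math.pi

    area0 = 4.0 * r0 * t0  # rectangle block coefficient
    mass = rho * h * (area0 * F["F110"] + pi * r0 * r0 * F["F200"])
    first = rho * h * h * (area0 * F["F111"] + pi * r0 * r0 * F["F201"])
    zbar = first / mass

    # cross-section second moments, stacked:
    #   about the depth axis (int y^2 dA): pi/4 r^4 + 4/3 t r^3
    #   about the width axis (int x^2 dA): pi/4 r^4 + pi t^2 r^2
    #                                      + 8/3 t r^3 + 4/3 t^3 r
    jx = rho * h * (pi / 4.0 * r0**4 * F["F400"] + 4.0 / 3.0 * t0 * r0**3 * F["F310"])
    jy = rho * h * (
        pi / 4.0 * r0**4 * F["F400"]
        + pi * t0 * t0 * r0 * r0 * F["F220"]
        + 8.0 / 3.0 * t0 * r0**3 * F["F310"]
        + 4.0 / 3.0 * t0**3 * r0 * F["F130"]
    )
    az2 = rho * h**3 * (area0 * F["F112"] + pi * r0 * r0 * F["F202"])

    inertia = np.diag([jx + az2, jy + az2, jx + jy])
    return RigidBodyProperties(mass, np.array([0.0, 0.0, zbar]), inertia)


def _frustum(r0: float, r1: float, h: float, rho: float) -> RigidBodyProperties:
    """Conical frustum (both bounding stadia circles), r(z) linear."""
    d = r1 - r0
    pi = math.pi
    # int_0^1 (r0 + d*u)^2 u^k du, k = 0, 1, 2; and int r^4
    i2_0 = r0 * r0 + r0 * d + d * d / 3.0
    i2_1 = r0 * r0 / 2.0 + 2.0 * r0 * d / 3.0 + d * d / 4.0
    i2_2 = r0 * r0 / 3.0 + r0 * d / 2.0 + d * d / 5.0
    i4 = (
        r0**4 + 2.0 * r0**3 * d + 2.0 * r0 * r0 * d * d
        + r0 * d**3 + d**4 / 5.0
    )
    mass = rho * pi * h * i2_0
    zbar = h * i2_1 / i2_0 if i2_0 > 0 else 0.5 * h
    jz = rho * pi / 2.0 * h * i4
    jxy = rho * (pi / 4.0 * h * i4 + pi * h**3 * i2_2)
    inertia = np.diag([jxy, jxy, jz])
    return RigidBodyProperties(mass, np.array([0.0, 0.0, zbar]), inertia)


_FLIP = np.diag([1.0, -1.0, -1.0])  # pi rotation about x


def stadium_solid_properties(solid: StadiumSolid) -> RigidBodyProperties:
    """Mass, COM, and inertia of a stadium solid about the centre of its
    bottom stadium, in the solid's local frame (x along the width axis,
    z longitudinal).

    Dispatch: the generic closed forms need a non-degenerate bottom
    stadium; if only the bottom is a circle the solid is evaluated upside
    down and transported back, and if both bounds are circles the frustum
    forms apply.
    """
    b, t = solid.bottom, solid.top
    h, rho = solid.height, solid.density
    if b.is_circle and t.is_circle:
        return _frustum(b.radius, t.radius, h, rho)
    if b.is_circle and b.radius > 0 and t.radius > 0:
        # swap the stadia: compute the flipped solid, then map back with a
        # pi rotation about x placed at the top of the original solid
        flipped = _generic_stadium_solid(
            t.radius, t.thickness, b.radius, b.thickness, h, rho
        )
        return transport_properties(
            flipped, FrameTransform(_FLIP, np.array([0.0, 0.0, h]))
        )
    if b.radius <= 0 or t.radius <= 0:
        if b.area == 0.0 and t.area == 0.0:
            return RigidBodyProperties(0.0, np.zeros(3), np.zeros((3, 3)))
        raise GeometryError(
            f"solid {solid.label!r}: a bounding stadium with zero radius and "
            "non-zero thickness is not supported"
        )
    return _generic_stadium_solid(
        b.radius, b.thickness, t.radius, t.thickness, h, rho
    )


def semiellipsoid_properties(e: Semiellipsoid) -> RigidBodyProperties:
    """Mass, COM, and inertia of a half-ellipsoid about the centre of its
    base ellipse, in the solid's local frame.

    Each half-ellipsoid integral is half the full-ellipsoid one, so about
    the base centre I_xx = m (b^2 + c^2)/5 etc.; the COM sits at 3c/8.
    """
    m = e.density * 2.0 / 3.0 * math.pi * e.a * e.b * e.c
    zbar = 3.0 * e.c / 8.0
    ixx = m * (e.b**2 + e.c**2) / 5.0
    iyy = m * (e.a**2 + e.c**2) / 5.0
    izz = m * (e.a**2 + e.b**2) / 5.0
    return RigidBodyProperties(
        m, np.array([0.0, 0.0, zbar]), np.diag([ixx, iyy, izz])
    )
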