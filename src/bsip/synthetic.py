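"""Synthetic anthropometry and a brute-force mass-property oracle.

:func:`generate_synthetic_measurements` emits complete, valid measurement
sets anchored to a plausible adult template (stature about 1.8 m) so the
whole pipeline can run without any subject data.  Scales and left/right
jitter are applied in a constraint-preserving way: one length factor per
limb side keeps every cumulative length block strictly increasing, and a
single girth factor per level multiplies the perimeter, width, and depth
together so every measured p/w ratio stays inside the physical stadium
range (2, pi) by construction.

:func:`numeric_mass_properties_oracle` computes a solid's mass, COM, and
inertia by numerical quadrature over its volume, on an integration route
independent of the closed forms in :mod:`bsip.solids`: the stadium cross
section is integrated with the trigonometric substitution y = r sin(phi)
(strip extent X(phi) = t + r cos(phi)), and sections are stacked with
Gauss-Legendre nodes along z.  Error decreases with ``resolution`` (the
node count per dimension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import scheme
from .measurements import MeasurementSet
from .solids import RigidBodyProperties, Semiellipsoid, StadiumSolid

__all__ = [
    "FixtureParams",
    "ADULT_TEMPLATE",
    "generate_synthetic_measurements",
    "numeric_mass_properties_oracle",
]

# Template subject: lengths, perimeters, widths, depths in metres.
# Stature ~1.8 m; girths chosen so the Dempster densities give a total
# mass well inside the adult range.
_TORSO_TEMPLATE = {
    "Ls1L": 0.12, "Ls2L": 0.24, "Ls3L": 0.38, "Ls4L": 0.50, "Ls5L": 0.60,
    "Ls6L": 0.14, "Ls7L": 0.18, "Ls8L": 0.29,
    "Ls0p": 0.94, "Ls1p": 0.85, "Ls2p": 0.83, "Ls3p": 0.95,
    "Ls5p": 0.38, "Ls6p": 0.58, "Ls7p": 0.58,
    "Ls0w": 0.34, "Ls1w": 0.30, "Ls2w": 0.29, "Ls3w": 0.33, "Ls4w": 0.42,
    "Ls4d": 0.22,
}
_ARM_TEMPLATE = {  # keys with chain letter '#'
    "L#2L": 0.30, "L#3L": 0.37, "L#4L": 0.55,
    "L#5L": 0.07, "L#6L": 0.115, "L#7L": 0.19,
    "L#0p": 0.36, "L#1p": 0.305, "L#2p": 0.275, "L#3p": 0.275,
    "L#4p": 0.175, "L#5p": 0.245, "L#6p": 0.23, "L#7p": 0.17,
    "L#4w": 0.057, "L#5w": 0.088, "L#6w": 0.088, "L#7w": 0.073,
}
_LEG_TEMPLATE = {
    "L#1L": 0.10, "L#3L": 0.44, "L#4L": 0.58, "L#5L": 0.82,
    "L#6L": 0.06, "L#8L": 0.16, "L#9L": 0.235,
    "L#1p": 0.60, "L#2p": 0.53, "L#3p": 0.385, "L#4p": 0.37,
    "L#5p": 0.225, "L#6p": 0.335, "L#7p": 0.25, "L#8p": 0.24,
    "L#9p": 0.155,
    "L#8w": 0.094, "L#9w": 0.066,
    "L#6d": 0.13,
}

ADULT_TEMPLATE: dict[str, float] = dict(_TORSO_TEMPLATE)
for _chain, _tpl in (("a", _ARM_TEMPLATE), ("b", _ARM_TEMPLATE),
                     ("j", _LEG_TEMPLATE), ("k", _LEG_TEMPLATE)):
    for _key, _value in _tpl.items():
        ADULT_TEMPLATE[_key.replace("#", _chain)] = _value
assert set(ADULT_TEMPLATE) == set(scheme.MEASUREMENT_NAMES)


@dataclass(frozen=True)
class FixtureParams:
    """Controls for the synthetic subject.

    ``stature_scale`` multiplies every length, ``girth_scale`` every
    perimeter/width/depth; ``asymmetry_jitter`` is the maximum fractional
    left/right perturbation (0 gives an exactly symmetric subject)."""

    stature_scale: float = 1.0
    girth_scale: float = 1.0
    asymmetry_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stature_scale <= 0 or self.girth_scale <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.asymmetry_jitter <= 0.2:
            raise ValueError("asymmetry_jitter must lie in [0, 0.2]")


def generate_synthetic_measurements(
    params: FixtureParams = FixtureParams(),
) -> MeasurementSet:
    """A complete, valid, deterministic-per-seed measurement set."""
    rng = np.random.default_rng(params.seed)
    values: dict[str, float] = {}

    def jitter() -> float:
        return 1.0 + params.asymmetry_jitter * rng.uniform(-1.0, 1.0)

    # one length factor and one per-level girth factor per limb side; the
    # rng is always advanced identically so seeds map to stable subjects
    chain_length_factor = {c: jitter() for c in ("a", "b", "j", "k")}
    level_girth_factor = {
        (c, lvl): jitter()
        for c in ("a", "b", "j", "k")
        for lvl in range(10)
    }

    for name in scheme.MEASUREMENT_NAMES:
        base = ADULT_TEMPLATE[name]
        chain, level, mtype = name[1], int(name[2]), name[3]
        if mtype == "L":
            value = base * params.stature_scale
            if chain in chain_length_factor:
                value *= chain_length_factor[chain]
        else:
            value = base * params.girth_scale
            if chain in chain_length_factor:
                value *= level_girth_factor[(chain, level)]
        values[name] = value
    return MeasurementSet(values)


# ---------------------------------------------------------------------------
# numerical oracle
# ---------------------------------------------------------------------------

def _stadium_section_integrals(r, t, nodes, weights):
    """Area, int x^2 dA, int y^2 dA of a stadium by quadrature over
    y = r sin(phi); the strip half-extent is X(phi) = t + r cos(phi)."""
    phi = 0.5 * np.pi * nodes  # phi in (-pi/2, pi/2)
    w = 0.5 * np.pi * weights
    cos, sin = np.cos(phi), np.sin(phi)
    X = t + r * cos
    dy = r * cos  # dy/dphi
    area = np.sum(w * 2.0 * X * dy)
    ix2 = np.sum(w * (2.0 / 3.0) * X**3 * dy)           # int x^2 dA
    iy2 = np.sum(w * 2.0 * X * (r * sin) ** 2 * dy)     # int y^2 dA
    return area, ix2, iy2


def numeric_mass_properties_oracle(
    solid: StadiumSolid | Semiellipsoid, resolution: int = 64
) -> RigidBodyProperties:
    """Mass, COM, and inertia about the bottom/base centre in the solid's
    local frame, by volume quadrature with ``resolution`` nodes per
    dimension."""
    nodes, weights = np.polynomial.legendre.leggauss(resolution)
    if isinstance(solid, Semiellipsoid):
        c = solid.c
        z = 0.5 * c * (nodes + 1.0)
        wz = 0.5 * c * weights
        shrink = np.sqrt(np.maximum(0.0, 1.0 - (z / c) ** 2))
        aa, bb = solid.a * shrink, solid.b * shrink
        area = np.pi * aa * bb
        ix2 = np.pi / 4.0 * aa**3 * bb
        iy2 = np.pi / 4.0 * aa * bb**3
    else:
        h = solid.height
        z = 0.5 * h * (nodes + 1.0)
        wz = 0.5 * h * weights
        frac = z / h
        r = solid.bottom.radius + (solid.top.radius - solid.bottom.radius) * frac
        t = (
            solid.bottom.thickness
            + (solid.top.thickness - solid.bottom.thickness) * frac
        )
        area = np.empty_like(z)
        ix2 = np.empty_like(z)
        iy2 = np.empty_like(z)
        for i in range(len(z)):
            area[i], ix2[i], iy2[i] = _stadium_section_integrals(
                r[i], t[i], nodes, weights
            )

    rho = solid.density
    mass = rho * np.sum(wz * area)
    zbar = rho * np.sum(wz * area * z) / mass
    izz = rho * np.sum(wz * (ix2 + iy2))
    ixx = rho * np.sum(wz * (iy2 + area * z**2))
    iyy = rho * np.sum(wz * (ix2 + area * z**2))
    return RigidBodyProperties(
        mass, np.array([0.0, 0.0, zbar]), np.diag([ixx, iyy, izz])
    )
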