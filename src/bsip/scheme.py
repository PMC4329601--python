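"""Declarative description of the body scheme.

Everything the model knows about the *structure* of the human lives here,
in plain tables: the 95 measurement names, how each of the 45 levels is
built from measurements, how the 40 solids stack into the 11 segments,
the kinematic tree with its 21 joint angles, and the default segmental
densities.  The assembly code in :mod:`bsip.human` only interprets these
tables, so the scheme can be audited (or corrected) without touching any
computation.

Naming follows the measurement convention ``L<chain><level><type>``:
chain ``s`` is the torso midline, ``a``/``b`` the left/right arm, ``j``/
``k`` the left/right leg; the type is ``L`` (length from the chain's
reference level), ``p`` (perimeter), ``w`` (mediolateral width), or ``d``
(anteroposterior depth).  Lengths are cumulative within the blocks of the
length-measurement table, not per-solid heights: torso lengths restart at
the acromion (Ls5), arm lengths at the wrist (La4/Lb4), and foot lengths
at the ankle (Lj5/Lk5).

Levels without a measured length are placed by the half-length rules: the
mid upper arm is halfway down to the elbow (La1L = La2L/2), the mid-thigh
halfway between crotch and knee, and the arch of the foot halfway between
heel and ball.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# measurement inventory (95 names)
# ---------------------------------------------------------------------------

_TORSO_MEASUREMENTS = (
    "Ls1L", "Ls2L", "Ls3L", "Ls4L", "Ls5L", "Ls6L", "Ls7L", "Ls8L",
    "Ls0p", "Ls1p", "Ls2p", "Ls3p", "Ls5p", "Ls6p", "Ls7p",
    "Ls0w", "Ls1w", "Ls2w", "Ls3w", "Ls4w",
    "Ls4d",
)

def _arm_measurements(c: str) -> tuple[str, ...]:
    return (
        f"L{c}2L", f"L{c}3L", f"L{c}4L", f"L{c}5L", f"L{c}6L", f"L{c}7L",
        f"L{c}0p", f"L{c}1p", f"L{c}2p", f"L{c}3p", f"L{c}4p", f"L{c}5p",
        f"L{c}6p", f"L{c}7p",
        f"L{c}4w", f"L{c}5w", f"L{c}6w", f"L{c}7w",
    )

def _leg_measurements(c: str) -> tuple[str, ...]:
    return (
        f"L{c}1L", f"L{c}3L", f"L{c}4L", f"L{c}5L", f"L{c}6L", f"L{c}8L",
        f"L{c}9L",
        f"L{c}1p", f"L{c}2p", f"L{c}3p", f"L{c}4p", f"L{c}5p", f"L{c}6p",
        f"L{c}7p", f"L{c}8p", f"L{c}9p",
        f"L{c}8w", f"L{c}9w",
        f"L{c}6d",
    )

#: The complete measurement inventory, in file order.
MEASUREMENT_NAMES: tuple[str, ...] = (
    _TORSO_MEASUREMENTS
    + _arm_measurements("a")
    + _arm_measurements("b")
    + _leg_measurements("j")
    + _leg_measurements("k")
)

#: Optional keys allowed in a measurement file besides the 95 names.
TOTAL_MASS_KEY = "total_mass"
UNIT_CONVERSION_KEY = "unit_conversion"

# ---------------------------------------------------------------------------
# levels
# ---------------------------------------------------------------------------
# Each level: (label, builder, position).
#   builder: how the level's stadium is made from measurements --
#     ("pw", p_key, w_key)   perimeter + width stadium
#     ("pd", p_key, d_key)   perimeter + the measured depth standing in for
#                            the width of a 90deg-rotated (anteroposterior)
#                            stadium -- the heels
#     ("wd", w_key, d_key)   width + depth stadium (the shoulders, where a
#                            perimeter cannot be measured)
#     ("p", p_key)           circle from a perimeter
#     ("acromion",)          internal wide stadium topping the shoulder
#                            solid: r = 0.57 r_Ls4, t = w_Ls4/2 - r
#     ("hip",)               internal hip-joint circle: r = sqrt(r_Ls0 *
#                            w_Ls0)/2
#     ("apex",)              no cross section (top of the head)
#   position: ((coef, length_key), ...) -- the level's longitudinal
#     coordinate along its chain, measured from the chain's base level, is
#     sum(coef * measurement).

LEVELS: dict[str, tuple] = {}

def _L(label, builder, position):
    LEVELS[label] = (builder, tuple(position))

_L("Ls0", ("pw", "Ls0p", "Ls0w"), [])                     # hip joint centre
_L("Ls1", ("pw", "Ls1p", "Ls1w"), [(1, "Ls1L")])          # umbilicus
_L("Ls2", ("pw", "Ls2p", "Ls2w"), [(1, "Ls2L")])          # lowest front rib
_L("Ls3", ("pw", "Ls3p", "Ls3w"), [(1, "Ls3L")])          # nipple
_L("Ls4", ("wd", "Ls4w", "Ls4d"), [(1, "Ls4L")])          # shoulder
_L("Ls5w", ("acromion",), [(1, "Ls5L")])                  # acromion, wide (top of s4)
_L("Ls5", ("p", "Ls5p"), [(1, "Ls5L")])                   # acromion, neck circle
_L("Ls6", ("p", "Ls6p"), [(1, "Ls5L"), (1, "Ls6L")])      # nose
_L("Ls7", ("p", "Ls7p"), [(1, "Ls5L"), (1, "Ls7L")])      # ear
_L("Ls8", ("apex",), [(1, "Ls5L"), (1, "Ls8L")])          # top of head

for _c in ("a", "b"):
    _L(f"L{_c}0", ("p", f"L{_c}0p"), [])                          # shoulder joint
    _L(f"L{_c}1", ("p", f"L{_c}1p"), [(0.5, f"L{_c}2L")])         # mid upper arm
    _L(f"L{_c}2", ("p", f"L{_c}2p"), [(1, f"L{_c}2L")])           # elbow joint
    _L(f"L{_c}3", ("p", f"L{_c}3p"), [(1, f"L{_c}3L")])           # max forearm
    _L(f"L{_c}4", ("pw", f"L{_c}4p", f"L{_c}4w"), [(1, f"L{_c}4L")])  # wrist
    _L(f"L{_c}5", ("pw", f"L{_c}5p", f"L{_c}5w"),
       [(1, f"L{_c}4L"), (1, f"L{_c}5L")])                        # base of thumb
    _L(f"L{_c}6", ("pw", f"L{_c}6p", f"L{_c}6w"),
       [(1, f"L{_c}4L"), (1, f"L{_c}6L")])                        # knuckles
    _L(f"L{_c}7", ("pw", f"L{_c}7p", f"L{_c}7w"),
       [(1, f"L{_c}4L"), (1, f"L{_c}7L")])                        # fingernails

for _c in ("j", "k"):
    _L(f"L{_c}0", ("hip",), [])                                   # hip joint centre
    _L(f"L{_c}1", ("p", f"L{_c}1p"), [(1, f"L{_c}1L")])           # crotch
    _L(f"L{_c}2", ("p", f"L{_c}2p"),
       [(0.5, f"L{_c}1L"), (0.5, f"L{_c}3L")])                    # mid-thigh
    _L(f"L{_c}3", ("p", f"L{_c}3p"), [(1, f"L{_c}3L")])           # knee joint
    _L(f"L{_c}4", ("p", f"L{_c}4p"), [(1, f"L{_c}4L")])           # max calf
    _L(f"L{_c}5", ("p", f"L{_c}5p"), [(1, f"L{_c}5L")])           # ankle joint
    _L(f"L{_c}6", ("pd", f"L{_c}6p", f"L{_c}6d"),
       [(1, f"L{_c}5L"), (1, f"L{_c}6L")])                        # heel
    _L(f"L{_c}7", ("p", f"L{_c}7p"),
       [(1, f"L{_c}5L"), (0.5, f"L{_c}6L"), (0.5, f"L{_c}8L")])   # arch
    _L(f"L{_c}8", ("pw", f"L{_c}8p", f"L{_c}8w"),
       [(1, f"L{_c}5L"), (1, f"L{_c}8L")])                        # ball
    _L(f"L{_c}9", ("pw", f"L{_c}9p", f"L{_c}9w"),
       [(1, f"L{_c}5L"), (1, f"L{_c}9L")])                        # toe nails

#: Internal acromion stadium: radius as a fraction of the shoulder radius.
ACROMION_RADIUS_RATIO = 0.57

# ---------------------------------------------------------------------------
# solids
# ---------------------------------------------------------------------------
#: (solid label, kind, bottom level, top level); bottom is the proximal
#: level.  The cranium is the single semi-ellipsoid.
SOLIDS: tuple[tuple[str, str, str, str], ...] = (
    ("s0", "stadium", "Ls0", "Ls1"),
    ("s1", "stadium", "Ls1", "Ls2"),
    ("s2", "stadium", "Ls2", "Ls3"),
    ("s3", "stadium", "Ls3", "Ls4"),
    ("s4", "stadium", "Ls4", "Ls5w"),
    ("s5", "stadium", "Ls5", "Ls6"),
    ("s6", "stadium", "Ls6", "Ls7"),
    ("s7", "semiellipsoid", "Ls7", "Ls8"),
) + tuple(
    (f"{c}{i}", "stadium", f"L{c}{i}", f"L{c}{i + 1}")
    for c in ("a", "b")
    for i in range(7)
) + tuple(
    (f"{c}{i}", "stadium", f"L{c}{i}", f"L{c}{i + 1}")
    for c in ("j", "k")
    for i in range(9)
)

# ---------------------------------------------------------------------------
# segments and kinematic tree
# ---------------------------------------------------------------------------
#: label -> (parent, solids, stack direction along the parent-aligned z
#: axis at zero configuration: +1 for the torso chain, -1 for the hanging
#: limbs)
SEGMENTS: dict[str, tuple[str | None, tuple[str, ...], int]] = {
    "P": (None, ("s0", "s1"), +1),
    "T": ("P", ("s2",), +1),
    "C": ("T", ("s3", "s4", "s5", "s6", "s7"), +1),
    "A1": ("C", ("a0", "a1"), -1),
    "A2": ("A1", ("a2", "a3", "a4", "a5", "a6"), -1),
    "B1": ("C", ("b0", "b1"), -1),
    "B2": ("B1", ("b2", "b3", "b4", "b5", "b6"), -1),
    "J1": ("P", ("j0", "j1", "j2"), -1),
    "J2": ("J1", ("j3", "j4", "j5", "j6", "j7", "j8"), -1),
    "K1": ("P", ("k0", "k1", "k2"), -1),
    "K2": ("K1", ("k3", "k4", "k5", "k6", "k7", "k8"), -1),
}

SEGMENT_ORDER = tuple(SEGMENTS)

#: Joint angles per segment, listed in body-fixed X-Y-Z order.  Every
#: child is rotated relative to its parent by Rx then Ry then Rz about its
#: own (body-fixed) axes; segments with fewer angles keep the same order.
#: The pelvis angles orient the whole body in the fixed frame.
JOINT_ANGLES: dict[str, tuple[tuple[str, str], ...]] = {
    "P": (("somersault", "x"), ("tilt", "y"), ("twist", "z")),
    "T": (("PTsagittalFlexion", "x"),),
    "C": (
        ("TCsagittalSpinalFlexion", "x"),
        ("TClateralSpinalFlexion", "y"),
        ("TCspinalTorsion", "z"),
    ),
    "A1": (("CA1extension", "x"), ("CA1adduction", "y"), ("CA1rotation", "z")),
    "A2": (("A1A2extension", "x"),),
    "B1": (("CB1extension", "x"), ("CB1abduction", "y"), ("CB1rotation", "z")),
    "B2": (("B1B2extension", "x"),),
    "J1": (("PJ1extension", "x"), ("PJ1adduction", "y")),
    "J2": (("J1J2flexion", "x"),),
    "K1": (("PK1extension", "x"), ("PK1abduction", "y")),
    "K2": (("K1K2flexion", "x"),),
}

#: The 21 configuration-variable names, in tree order.
CONFIG_NAMES: tuple[str, ...] = tuple(
    name for seg in SEGMENT_ORDER for name, _axis in JOINT_ANGLES[seg]
)

_PI = math.pi
#: Conservative physiological bounds (radians).  The model itself places
#: no hard anatomical limits; these are data and can be overridden.
CONFIG_BOUNDS: dict[str, tuple[float, float]] = {
    "somersault": (-_PI, _PI),
    "tilt": (-_PI, _PI),
    "twist": (-_PI, _PI),
    "PTsagittalFlexion": (-_PI / 2, _PI / 2),
    "TCsagittalSpinalFlexion": (-_PI / 2, _PI / 2),
    "TClateralSpinalFlexion": (-_PI / 2, _PI / 2),
    "TCspinalTorsion": (-_PI / 2, _PI / 2),
    "CA1extension": (-_PI, _PI / 2),
    "CA1adduction": (-_PI, _PI / 2),
    "CA1rotation": (-_PI, _PI),
    "CB1extension": (-_PI, _PI / 2),
    "CB1abduction": (-_PI / 2, _PI),
    "CB1rotation": (-_PI, _PI),
    "A1A2extension": (-_PI, 0.0),
    "B1B2extension": (-_PI, 0.0),
    "PJ1extension": (-_PI, _PI / 2),
    "PJ1adduction": (-_PI / 2, _PI / 2),
    "PK1extension": (-_PI, _PI / 2),
    "PK1abduction": (-_PI / 2, _PI / 2),
    "J1J2flexion": (0.0, _PI),
    "K1K2flexion": (0.0, _PI),
}

# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------
#: Dempster's cadaver-derived segmental densities (kg/m^3), assigned per
#: solid as in Yeadon's model: head-neck 1.11, shoulders 1.04, thorax
#: 0.92, abdominal-pelvic 1.01, upper arm 1.07, forearm 1.13, hand 1.16,
#: thigh 1.05, lower leg 1.09, foot 1.10 (g/cm^3).
DEMPSTER_DENSITIES: dict[str, float] = {}
for _s, _rho in [
    ("s0", 1010.0), ("s1", 1010.0),
    ("s2", 920.0), ("s3", 920.0),
    ("s4", 1040.0),
    ("s5", 1110.0), ("s6", 1110.0), ("s7", 1110.0),
]:
    DEMPSTER_DENSITIES[_s] = _rho
for _c in ("a", "b"):
    for _i, _rho in [(0, 1070.0), (1, 1070.0), (2, 1130.0), (3, 1130.0),
                     (4, 1160.0), (5, 1160.0), (6, 1160.0)]:
        DEMPSTER_DENSITIES[f"{_c}{_i}"] = _rho
for _c in ("j", "k"):
    for _i, _rho in [(0, 1050.0), (1, 1050.0), (2, 1050.0),
                     (3, 1090.0), (4, 1090.0),
                     (5, 1100.0), (6, 1100.0), (7, 1100.0), (8, 1100.0)]:
        DEMPSTER_DENSITIES[f"{_c}{_i}"] = _rho

SOLID_LABELS: tuple[str, ...] = tuple(s[0] for s in SOLIDS)

#: Number of distinct level stations.  The acromion station carries two
#: cross sections (the wide internal stadium "Ls5w" topping the shoulder
#: solid, and the neck circle "Ls5") but is one level.
N_LEVELS = len(LEVELS) - 1

# internal consistency of the tables
assert len(MEASUREMENT_NAMES) == 95
assert len(set(MEASUREMENT_NAMES)) == 95
assert N_LEVELS == 45
assert len(SOLIDS) == 40
assert len(SEGMENTS) == 11
assert len(CONFIG_NAMES) == 21
assert set(CONFIG_BOUNDS) == set(CONFIG_NAMES)
assert set(DEMPSTER_DENSITIES) == set(SOLID_LABELS)
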