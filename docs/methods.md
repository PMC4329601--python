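# Methods

## The geometric model

The body is modelled after Yeadon's stadium-solid formulation: 11 rigid
segments (pelvis P; torso T; chest-head C; upper/lower arms A1, A2 on the
left and B1, B2 on the right; thigh and shank-plus-foot J1, J2 left and
K1, K2 right) composed of 40 solids bounded by 45 transverse *levels*.
Each level is a stadium — a `2t × 2r` rectangle capped by two semicircles
of radius `r` — characterised by any two of perimeter `p = 4t + 2πr`,
width `w = 2(t + r)`, depth `d = 2r`, `r`, and `t`.  A solid is the loft
between two adjacent levels with `r(z)` and `t(z)` linear in the
longitudinal coordinate; the cranium is a semi-ellipsoid.  Which
attribute pair defines each level, how the 95 measurements map to
levels, the per-solid Dempster densities, the segment partition of the
solids, and the 21-joint-angle kinematic tree are all encoded as plain
data tables in `bsip/scheme.py` so they can be audited independently of
the computation.

Lengths are measured cumulatively from a per-chain reference level
(torso lengths from the hip level, restarting at the acromion; arm
lengths from the shoulder, restarting at the wrist; leg lengths from the
hip joint, with the foot measured from the ankle); per-solid heights are
the differences, and a non-increasing pair is reported as a measurement
error naming the offending levels.  Three levels are positioned without
a measurement: mid upper arm (half the shoulder-elbow length),
mid-thigh (midway between crotch and knee), and the arch of the foot
(midway between heel and ball).  Two cross sections are internal: the
wide acromion stadium topping the shoulder solid
(`r = 0.57 r_shoulder`, `t = w_shoulder/2 − r`) and the hip-joint
circles at the top of each thigh, taken as
`r = ½ √(r_hip-level · w_hip-level)`.  The published source for the
latter prints the relation with its radical typographically lost; the
square-root reading is the only dimensionally consistent one and is
adopted here.

Measured perimeter/width pairs must satisfy `2 < p/w < π` to describe a
stadium.  Out-of-range pairs are downgraded to a circle — recovered from
the perimeter when one was measured, else from the width — with a
warning, never an exception, since field measurements routinely brush
these limits.  The boundary values are degenerate but valid (a line
segment at 2, a circle at π).  The heels are the one anteroposterior
cross section: the measured "depth" there is the width of a stadium
rotated 90°, and the package stores it as an ordinary mediolateral
stadium plus a quarter-turn applied at assembly.

## Closed-form solid properties

With `r(ẑ) = r₀(1 + aẑ)`, `t(ẑ) = t₀(1 + bẑ)` (`ẑ = z/h`,
`a = r₁/r₀ − 1`, `b = t₁/t₀ − 1`), every mass property is an exact
polynomial integral: section area `A = 4rt + πr²`, section second
moments `∫y²dA = πr⁴/4 + 4tr³/3` and
`∫x²dA = πr⁴/4 + πt²r² + 8tr³/3 + 4t³r/3`, stacked over `ẑ` with the
helper integrals `F(m,n,k) = ∫₀¹ (1+aẑ)ᵐ(1+bẑ)ⁿ ẑᵏ dẑ`, which are short
fixed polynomials in `a, b` (derived symbolically once, hard-coded in
`bsip/solids.py`).  No small-thickness approximation is used anywhere.
Forming `b` divides by `t₀`, so a solid whose *bottom* stadium is a
circle is evaluated upside down (stadia swapped) and the result
transported back by a half-turn; a solid bounded by two circles is a
conical frustum with its own direct forms.  A bounding stadium with zero
radius but non-zero thickness (a zero-area line, unreachable from real
measurements) is rejected rather than approximated.  The semi-ellipsoid
uses the half-ellipsoid forms about its base centre
(`m = ⅔πabcρ`, COM at `3c/8`, `I_xx = m(b² + c²)/5`, cyclic).

Frame transport of `(m, COM, I)` applies `I → R I Rᵀ` and the
generalised parallel-axis theorem (two-step: to the COM, then to the new
reference point), so rotations preserve the spectrum exactly and
reference-point moves are exact.

## Kinematics and conventions

The global frame has its origin at the bottom centre of the lowest
pelvis solid (the midpoint of the two hip joint centres), z vertical, x
mediolateral toward the left hip, y posterior.  In the zero
configuration every segment's local frame coincides with the global
frame; the torso chain stacks upward and the limbs hang downward
(internally, a limb solid's own frame is related to its segment frame by
a half-turn about x — a representation choice with no observable
effect).  Each child segment rotates about its joint centre relative to
its parent by body-fixed X-Y-Z angles; joints with fewer angles keep the
same order.  Joint centres sit at the centre of the segment's base
stadium, except the shoulders (the most lateral points of the shoulder
level) and the hips (`±¼ w_hip-level` along x, derived from the
measured hip stadium).  The torso–chest-head joint sits at the nipple
level.

The 21 configuration variables: `somersault`, `tilt`, `twist` orient the
pelvis in the fixed frame; `PTsagittalFlexion`;
`TCsagittalSpinalFlexion`, `TClateralSpinalFlexion`, `TCspinalTorsion`;
`CA1extension`, `CA1adduction`, `CA1rotation` (left shoulder, mirrored
as `CB1extension`, `CB1abduction`, `CB1rotation` on the right);
`A1A2extension`, `B1B2extension` (elbows); `PJ1extension`,
`PJ1adduction`, `PK1extension`, `PK1abduction` (hips); `J1J2flexion`,
`K1K2flexion` (knees).  Exactly four joints carry all three rotational
degrees of freedom (the pelvis-to-ground orientation, the spine at TC,
and both shoulders).  Signs follow the right-hand rule about the
parent-aligned axes: with the arms hanging, `CA1adduction = −π/2` raises
the left arm laterally to horizontal and `CB1abduction = +π/2` the
right; positive knee flexion folds the shank backwards.  All 21 angles
are independent; no left/right coupling is imposed.  The shipped angle
bounds are conservative physiological ranges expressed as data
(`scheme.CONFIG_BOUNDS`) — the geometry itself places no limits, and
users with other conventions can override them.  There are no wrist or
ankle joints.

## Densities and mass scaling

Dempster's cadaver-derived segmental densities are assigned per solid
(head-neck 1.11, shoulders 1.04, thorax 0.92, abdominal-pelvic 1.01,
upper arm 1.07, forearm 1.13, hand 1.16, thigh 1.05, lower leg 1.09,
foot 1.10 g/cm³) and are plain data.  Because mass is linear in density,
scaling all densities by `target/current` makes the model total match a
measured subject mass exactly (to floating-point summation accuracy),
scales every tensor entry by the same factor, and moves no COM; it is
no guarantee that individual segment estimates improve.  Unit tests
inject a uniform density so no correctness result depends on these
constants.

## Synthetic anthropometry

`bsip.synthetic` generates complete measurement sets from a fixed adult
template (stature ≈ 1.8 m, total mass ≈ 83 kg under the default
densities — a plausibility anchor, not population statistics).  Stature
and girth scales multiply the length and girth groups; left/right
asymmetry applies one length factor per limb side and one girth factor
per level, the latter multiplying a level's perimeter, width, and depth
together.  This construction keeps every cumulative length block
strictly increasing and every measured `p/w` ratio inside `(2, π)` for
any jitter up to the allowed 0.2, so generated subjects never trigger
the circle fallback.  What passing tests on these subjects shows is
internal consistency of the geometry, kinematics, and aggregation — not
anthropometric accuracy for real populations, which depends on
measurement quality and on how well stadium solids approximate a given
subject.

## Numerical choices and verification

The closed forms are verified against an independent quadrature oracle
that integrates each solid's volume on a different route: the stadium
section is integrated with the substitution `y = r sin φ` (strip
half-extent `t + r cos φ`), sections are stacked on Gauss–Legendre
nodes, and the error decreases with the node count.  Closed form and
oracle agree to ~1e−15 relative; the test suite requires ≤1e−8 on every
tensor entry over randomised sweeps, and the swapped-stadia degenerate
path is required to agree with the generic path evaluated at thickness
1e−9 to 1e−5.  Aggregation identities (segment sums equal the whole
body; inertia about the COM minimal in the positive-semidefinite order;
spectra invariant under rotation) are asserted at 1e−12.  Relative
tensor comparisons use the largest oracle entry as scale so that
exactly-zero products of inertia do not produce 0/0.

Whole-body tensors are reported about the global origin by default, with
about-COM and arbitrary point/axes variants computed by transport.  The
acceptance script uses a 40-solid model and a 100-solid oracle sweep at
resolution 48 — desk-scale sizes that complete in seconds.

## Known limitations

Stadium solids are a coarse model of hands and feet (the foot continues
along the shank axis); there are no wrist/ankle joints; density is
uniform within a solid; the left/right symmetrisation is optional and
off by default.  The configuration bounds are advisory data, not
anatomy.  The published model text leaves a few structural details to a
figure rather than prose (the exact measurement inventory and joint
naming); this package fixes them in `bsip/scheme.py` as documented
choices consistent with the printed counts and examples, and any
correction is a data edit, not a code change.
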