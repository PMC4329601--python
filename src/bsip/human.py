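"""Assembly and posing of the 11-segment human model.

The human is a kinematic tree rooted at the pelvis ``P``.  Each segment
owns a stack of solids; each child segment is attached to its parent at a
joint centre and rotated relative to it by body-fixed X-Y-Z angles drawn
from the 21 configuration variables.  The global frame has its origin at
the bottom centre of solid ``s0`` (the midpoint of the two hip joint
centres), z vertical, x mediolateral towards the left hip, y posterior;
with all angles zero every segment's local axes coincide with it.

Within a segment, the torso chain stacks its solids upward along +z while
the limbs hang downward: a limb solid's own frame (z from its proximal
stadium towards the distal one) is related to the segment frame by a
half-turn about x, and the anteroposterior heel stadia get an extra
quarter-turn about the longitudinal axis.

All aggregate quantities (whole body, any segment, any combination of
segments and solids) are obtained by transporting each solid's local
closed-form properties into the global frame and summing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from . import scheme
from .measurements import (
    DensityTable,
    MeasurementError,
    MeasurementSet,
    SolidSpec,
    SolidStackSpec,
    average_limbs,
    default_densities,
    resolve_levels,
    scale_densities_to_mass,
)
from .solids import (
    ANTEROPOSTERIOR,
    FrameTransform,
    RigidBodyProperties,
    Semiellipsoid,
    StadiumSolid,
    semiellipsoid_properties,
    stadium_solid_properties,
    transport_properties,
)

__all__ = [
    "ConfigurationError",
    "HumanModel",
    "build_human",
    "scale_human_by_mass",
    "parse_configuration_file",
]


class ConfigurationError(ValueError):
    """Unknown configuration variable or out-of-bounds angle."""


def _rot(axis: str, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    if axis == "x":
        return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


_HALF_TURN_X = _rot("x", math.pi)
_QUARTER_TURN_Z = _rot("z", math.pi / 2)


@dataclass(frozen=True)
class _PlacedSolid:
    """A solid with its constant placement inside its segment."""

    label: str
    segment: str
    local_props: RigidBodyProperties  # about bottom-stadium centre, solid frame
    in_segment: FrameTransform        # solid frame -> segment frame


@dataclass(frozen=True)
class Segment:
    """One rigid segment: its solids and its attachment to the parent."""

    label: str
    parent: str | None
    joint_center: np.ndarray  # in the parent's local frame (global for P)
    solids: tuple[_PlacedSolid, ...]
    angle_names: tuple[tuple[str, str], ...]  # (config name, axis), X-Y-Z order


def _solid_local_properties(spec: SolidSpec, density: float) -> RigidBodyProperties:
    if spec.kind == "semiellipsoid":
        r = spec.bottom.radius
        return semiellipsoid_properties(
            Semiellipsoid(r, r, spec.height, density, spec.label)
        )
    solid = StadiumSolid(spec.bottom, spec.top, spec.height, density, spec.label)
    return stadium_solid_properties(solid)


def _build_segments(
    stacks: SolidStackSpec, densities: DensityTable
) -> dict[str, Segment]:
    pos = stacks.positions
    w_ls4_half = stacks.stadia["Ls4"].width / 2.0
    hip_offset = 0.25 * stacks.stadia["Ls0"].width  # (t_Ls0 + r_Ls0) / 2

    #: joint-centre position of each segment in its parent's frame, and the
    #: level at the segment's own base
    joint_centers: dict[str, tuple[np.ndarray, str]] = {
        "P": (np.zeros(3), "Ls0"),
        "T": (np.array([0.0, 0.0, pos["Ls2"]]), "Ls2"),
        "C": (np.array([0.0, 0.0, pos["Ls3"] - pos["Ls2"]]), "Ls3"),
        "A1": (np.array([w_ls4_half, 0.0, pos["Ls4"] - pos["Ls3"]]), "La0"),
        "A2": (np.array([0.0, 0.0, -pos["La2"]]), "La2"),
        "B1": (np.array([-w_ls4_half, 0.0, pos["Ls4"] - pos["Ls3"]]), "Lb0"),
        "B2": (np.array([0.0, 0.0, -pos["Lb2"]]), "Lb2"),
        "J1": (np.array([hip_offset, 0.0, 0.0]), "Lj0"),
        "J2": (np.array([0.0, 0.0, -pos["Lj3"]]), "Lj3"),
        "K1": (np.array([-hip_offset, 0.0, 0.0]), "Lk0"),
        "K2": (np.array([0.0, 0.0, -pos["Lk3"]]), "Lk3"),
    }

    segments: dict[str, Segment] = {}
    for label, (parent, solid_labels, direction) in scheme.SEGMENTS.items():
        joint_center, base_level = joint_centers[label]
        base_z = pos[base_level]
        placed = []
        for solid_label in solid_labels:
            spec = stacks.solids[solid_label]
            bottom_level = dict((s[0], s[2]) for s in scheme.SOLIDS)[solid_label]
            offset = pos[bottom_level] - base_z
            if direction > 0:
                rotation = np.eye(3)
                origin = np.array([0.0, 0.0, offset])
            else:
                rotation = _HALF_TURN_X
                origin = np.array([0.0, 0.0, -offset])
            if spec.kind == "stadium":
                solid_orientation = StadiumSolid(
                    spec.bottom, spec.top, spec.height, 1.0, solid_label
                ).orientation
                if solid_orientation == ANTEROPOSTERIOR:
                    rotation = rotation @ _QUARTER_TURN_Z
            placed.append(
                _PlacedSolid(
                    label=solid_label,
                    segment=label,
                    local_props=_solid_local_properties(
                        spec, densities[spec.density_label]
                    ),
                    in_segment=FrameTransform(rotation, origin),
                )
            )
        segments[label] = Segment(
            label=label,
            parent=parent,
            joint_center=joint_center,
            solids=tuple(placed),
            angle_names=scheme.JOINT_ANGLES[label],
        )
    return segments


class HumanModel:
    """A posed, personalised human body.

    Construct with :func:`build_human`.  The model exposes whole-body
    mass, centre of mass, and inertia (global frame, about the global
    origin unless stated), per-segment and per-solid properties, combined
    properties of arbitrary label lists, and density scaling to a measured
    total mass.
    """

    def __init__(
        self,
        measurements: MeasurementSet,
        densities: DensityTable,
        stacks: SolidStackSpec,
        symmetric: bool,
        configuration: dict[str, float] | None = None,
    ) -> None:
        self.measurements = measurements
        self.densities = densities
        self.stacks = stacks
        self.symmetric = symmetric
        self.segments = _build_segments(stacks, densities)
        self._config = {name: 0.0 for name in scheme.CONFIG_NAMES}
        if configuration:
            for name, angle in configuration.items():
                self.set_configuration(name, angle)

    # -- configuration ----------------------------------------------------

    @property
    def configuration(self) -> dict[str, float]:
        return dict(self._config)

    def set_configuration(self, name: str, angle: float) -> "HumanModel":
        """Set one of the 21 joint angles (radians); returns self."""
        if name not in self._config:
            raise ConfigurationError(f"unknown configuration variable {name!r}")
        lo, hi = scheme.CONFIG_BOUNDS[name]
        if not (lo <= angle <= hi):
            raise ConfigurationError(
                f"{name} = {angle:.4g} rad outside bounds [{lo:.4g}, {hi:.4g}]"
            )
        self._config[name] = float(angle)
        return self

    def reset_configuration(self) -> "HumanModel":
        for name in self._config:
            self._config[name] = 0.0
        return self

    # -- kinematics --------------------------------------------------------

    def _segment_transforms(self) -> dict[str, FrameTransform]:
        """Global frame transform of every segment's local frame."""
        transforms: dict[str, FrameTransform] = {}
        for label in scheme.SEGMENT_ORDER:
            seg = self.segments[label]
            rel = np.eye(3)
            for angle_name, axis in seg.angle_names:
                rel = rel @ _rot(axis, self._config[angle_name])
            if seg.parent is None:
                transforms[label] = FrameTransform(rel, np.zeros(3))
            else:
                parent = transforms[seg.parent]
                transforms[label] = parent.compose(
                    FrameTransform(rel, seg.joint_center)
                )
        return transforms

    def _solid_global_properties(self) -> dict[str, RigidBodyProperties]:
        """Every solid's properties about the global origin, global frame."""
        seg_xf = self._segment_transforms()
        out: dict[str, RigidBodyProperties] = {}
        for label in scheme.SEGMENT_ORDER:
            xf = seg_xf[label]
            for ps in self.segments[label].solids:
                out[ps.label] = transport_properties(
                    ps.local_props, xf.compose(ps.in_segment), frame_tag="global"
                )
        return out

    # -- aggregate properties ---------------------------------------------

    def properties(self) -> RigidBodyProperties:
        """Whole-body properties about the global origin, global frame."""
        return _sum_properties(self._solid_global_properties().values())

    @property
    def mass(self) -> float:
        return self.properties().mass

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.properties().com

    @property
    def inertia(self) -> np.ndarray:
        """Whole-body inertia tensor about the global origin."""
        return self.properties().inertia

    @property
    def inertia_about_com(self) -> np.ndarray:
        return self.properties().about_com().inertia

    def solid_properties(self, label: str) -> RigidBodyProperties:
        """One solid's properties about the global origin, global frame."""
        props = self._solid_global_properties()
        if label not in props:
            raise KeyError(f"unknown solid {label!r}")
        return props[label]

    def segment_properties(self, label: str) -> RigidBodyProperties:
        """One segment's properties about the global origin, global frame."""
        if label not in self.segments:
            raise KeyError(f"unknown segment {label!r}")
        props = self._solid_global_properties()
        return _sum_properties(
            props[ps.label] for ps in self.segments[label].solids
        )

    def segment_mass(self, label: str) -> float:
        return self.segment_properties(label).mass

    def combine_inertia(
        self, labels: list[str] | tuple[str, ...]
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Combined (mass, COM, inertia about the combined COM) of a list
        of solid and/or segment labels, in the global frame.

        A solid may not be listed alongside the segment that contains it,
        and duplicates are rejected.  Read-only: the model is unchanged.
        """
        solid_labels: list[str] = []
        seen_segments: list[str] = []
        for label in labels:
            if label in self.segments:
                seen_segments.append(label)
                solid_labels.extend(
                    ps.label for ps in self.segments[label].solids
                )
            elif label in scheme.SOLID_LABELS:
                solid_labels.append(label)
            else:
                raise KeyError(f"unknown segment or solid {label!r}")
        for seg_label in seen_segments:
            for ps in self.segments[seg_label].solids:
                if ps.label in labels:
                    raise ValueError(
                        f"solid {ps.label!r} is part of segment {seg_label!r}; "
                        "specify one or the other"
                    )
        if len(set(solid_labels)) != len(solid_labels):
            raise ValueError("labels overlap")
        props = self._solid_global_properties()
        total = _sum_properties(props[s] for s in solid_labels).about_com()
        # about_com re-references the tensor to the combined COM; report the
        # COM in global coordinates
        com = _sum_properties(props[s] for s in solid_labels).com
        return total.mass, com, total.inertia

    def inertia_transformed(
        self, point=(0.0, 0.0, 0.0), rotation=None
    ) -> np.ndarray:
        """Whole-body inertia about ``point`` (global coordinates), with
        rows/columns along the axes of ``rotation`` (columns = new basis
        vectors expressed in the global frame)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper orthonormal")
        whole = self.properties().about_com()
        body = self.properties()
        d = body.com - np.asarray(point, dtype=float).reshape(3)
        shifted = whole.inertia + body.mass * (
            np.dot(d, d) * np.eye(3) - np.outer(d, d)
        )
        return R.T @ shifted @ R

    # -- density scaling ---------------------------------------------------

    def scale_by_mass(self, target_mass: float) -> "HumanModel":
        """A new model whose densities are scaled so the total mass equals
        ``target_mass``; geometry, COM positions, and the configuration
        are untouched."""
        if not target_mass > 0:
            raise MeasurementError("target mass must be positive")
        scaled = scale_densities_to_mass(self.densities, self.mass, target_mass)
        return HumanModel(
            self.measurements, scaled, self.stacks, self.symmetric, self._config
        )


def _sum_properties(props) -> RigidBodyProperties:
    mass = 0.0
    moment = np.zeros(3)
    inertia = np.zeros((3, 3))
    for p in props:
        mass += p.mass
        moment += p.mass * p.com
        inertia = inertia + p.inertia
    com = moment / mass if mass > 0 else np.zeros(3)
    return RigidBodyProperties(mass, com, inertia, "global")


def build_human(
    measurements: MeasurementSet,
    densities: DensityTable | None = None,
    symmetric: bool = False,
    configuration: dict[str, float] | None = None,
) -> HumanModel:
    """Assemble a :class:`HumanModel` from measurements.

    ``symmetric=True`` averages the left/right limb measurements first.
    ``densities`` defaults to the Dempster table; if the measurement set
    carries a subject ``total_mass`` the densities are scaled so the model
    matches it.
    """
    if symmetric:
        measurements = average_limbs(measurements)
    if densities is None:
        densities = default_densities()
    stacks = resolve_levels(measurements)
    model = HumanModel(measurements, densities, stacks, symmetric, configuration)
    if measurements.total_mass is not None:
        model = model.scale_by_mass(measurements.total_mass)
    return model


def scale_human_by_mass(model: HumanModel, target_mass: float) -> HumanModel:
    """Functional form of :meth:`HumanModel.scale_by_mass`."""
    return model.scale_by_mass(target_mass)


def parse_configuration_file(text: str) -> dict[str, float]:
    """Parse a YAML mapping of configuration variables to radians.

    Omitted variables default to zero; unknown names are an error (bounds
    are checked when the configuration is applied to a model).
    """
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed configuration file: {exc}") from exc
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration file must be a YAML mapping")
    config = {}
    for name, angle in raw.items():
        if name not in scheme.CONFIG_NAMES:
            raise ConfigurationError(f"unknown configuration variable {name!r}")
        if not isinstance(angle, (int, float)) or isinstance(angle, bool):
            raise ConfigurationError(f"angle {name!r} is not a number")
        config[str(name)] = float(angle)
    return config
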