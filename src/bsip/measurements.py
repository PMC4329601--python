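"""Measurement parsing, validation, and resolution into level stadia.

A measurement file is a YAML mapping whose keys are the 95 measurement
names (see :mod:`bsip.scheme`), all in metres, plus two optional keys:
``total_mass`` (kg, used for density scaling) and ``unit_conversion`` (a
factor multiplying every length, so files recorded in millimetres can set
``unit_conversion: 0.001``).

:func:`resolve_levels` turns a validated measurement set into concrete
geometry: one stadium (or the cranial semi-ellipsoid spec) per level and
one solid spec per pair of consecutive levels, with heights obtained by
differencing the cumulative length measurements within each measurement
block.  Measured perimeter/width pairs whose ratio falls outside the
physical stadium range (2, pi) are downgraded to circles with a warning,
never an exception.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import yaml

from . import scheme
from .solids import (
    ANTEROPOSTERIOR,
    MEDIOLATERAL,
    Stadium,
    stadium_from_attributes,
)

__all__ = [
    "MeasurementSet",
    "MeasurementError",
    "DensityTable",
    "SolidSpec",
    "SolidStackSpec",
    "parse_measurement_file",
    "write_measurement_file",
    "average_limbs",
    "resolve_levels",
    "default_densities",
    "scale_densities_to_mass",
]

log = logging.getLogger(__name__)


class MeasurementError(ValueError):
    """A measurement file or measurement set is invalid."""


@dataclass(frozen=True)
class MeasurementSet:
    """The 95 validated measurements (metres) and optional subject mass."""

    values: dict[str, float]
    total_mass: float | None = None

    def __post_init__(self) -> None:
        missing = [n for n in scheme.MEASUREMENT_NAMES if n not in self.values]
        unknown = [n for n in self.values if n not in scheme.MEASUREMENT_NAMES]
        if missing:
            raise MeasurementError(f"missing measurements: {', '.join(missing)}")
        if unknown:
            raise MeasurementError(f"unknown measurements: {', '.join(unknown)}")
        bad = [n for n, v in self.values.items() if not v > 0]
        if bad:
            raise MeasurementError(f"non-positive measurements: {', '.join(bad)}")
        if self.total_mass is not None and not self.total_mass > 0:
            raise MeasurementError("total_mass must be positive")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def parse_measurement_file(text: str) -> MeasurementSet:
    """Parse YAML measurement text into a validated :class:`MeasurementSet`.

    Unknown keys are rejected, missing keys reported by name, and every
    length is multiplied by the optional ``unit_conversion`` factor.
    """
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise MeasurementError(f"malformed measurement file: {exc}") from exc
    if not isinstance(raw, dict):
        raise MeasurementError("measurement file must be a YAML mapping")

    factor = raw.pop(scheme.UNIT_CONVERSION_KEY, 1.0)
    total_mass = raw.pop(scheme.TOTAL_MASS_KEY, None)
    values = {}
    for key, value in raw.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise MeasurementError(f"measurement {key!r} is not a number: {value!r}")
        values[str(key)] = float(value) * float(factor)
    if total_mass is not None:
        if not isinstance(total_mass, (int, float)) or isinstance(total_mass, bool):
            raise MeasurementError(f"{scheme.TOTAL_MASS_KEY} is not a number")
        total_mass = float(total_mass)
    return MeasurementSet(values, total_mass)


def write_measurement_file(m: MeasurementSet) -> str:
    """Emit the YAML dialect read by :func:`parse_measurement_file`
    (round-trip stable; lengths written in metres)."""
    lines = ["# anthropometric measurements (m)"]
    for name in scheme.MEASUREMENT_NAMES:
        lines.append(f"{name}: {m.values[name]!r}")
    if m.total_mass is not None:
        lines.append(f"{scheme.TOTAL_MASS_KEY}: {m.total_mass!r}")
    return "\n".join(lines) + "\n"


def average_limbs(m: MeasurementSet) -> MeasurementSet:
    """Impose left/right symmetry by replacing each left/right measurement
    pair (arms a/b, legs j/k) with its arithmetic mean.  Idempotent; torso
    measurements are untouched."""
    values = dict(m.values)
    for left_chain, right_chain in (("a", "b"), ("j", "k")):
        for name in scheme.MEASUREMENT_NAMES:
            if name[1] == left_chain:
                other = name[0] + right_chain + name[2:]
                mean = 0.5 * (values[name] + values[other])
                values[name] = mean
                values[other] = mean
    return replace(m, values=values)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityTable:
    """Density (kg/m^3) of each of the 40 solids, plus the factor applied
    so far by mass scaling."""

    values: dict[str, float]
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if set(self.values) != set(scheme.SOLID_LABELS):
            raise MeasurementError("density table must cover exactly the 40 solids")
        if any(not v > 0 for v in self.values.values()):
            raise MeasurementError("densities must be positive")

    def __getitem__(self, label: str) -> float:
        return self.values[label]


def default_densities() -> DensityTable:
    """Dempster's segmental densities as assigned per solid by Yeadon."""
    return DensityTable(dict(scheme.DEMPSTER_DENSITIES))


def uniform_densities(density: float = 1000.0) -> DensityTable:
    """A uniform density table (handy for tests and sensitivity checks)."""
    return DensityTable({label: density for label in scheme.SOLID_LABELS})


def scale_densities_to_mass(
    table: DensityTable, current_mass: float, target_mass: float
) -> DensityTable:
    """Scale every density by ``target_mass / current_mass`` so a model
    rebuilt with the result has total mass ``target_mass`` (mass is linear
    in density)."""
    if not current_mass > 0 or not target_mass > 0:
        raise MeasurementError("masses must be positive")
    f = target_mass / current_mass
    return DensityTable(
        {k: v * f for k, v in table.values.items()}, table.scale_factor * f
    )


# ---------------------------------------------------------------------------
# level resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolidSpec:
    """One resolved solid: its kind, bounding cross sections, and height."""

    label: str
    kind: str  # "stadium" | "semiellipsoid"
    bottom: Stadium | None
    top: Stadium | None
    height: float
    density_label: str = ""


@dataclass(frozen=True)
class SolidStackSpec:
    """Resolved geometry: every level stadium, every solid, and each
    level's longitudinal position along its chain."""

    stadia: dict[str, Stadium]
    positions: dict[str, float]
    solids: dict[str, SolidSpec]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _level_position(level: str, m: MeasurementSet) -> float:
    _builder, position = scheme.LEVELS[level]
    return sum(coef * m[key] for coef, key in position)


def _build_stadium(level: str, m: MeasurementSet, warn) -> Stadium | None:
    builder = scheme.LEVELS[level][0]
    kind = builder[0]
    if kind == "apex":
        return None
    if kind == "p":
        return stadium_from_attributes(
            perimeter=m[builder[1]], label=level, on_fallback=warn
        )
    if kind == "pw":
        return stadium_from_attributes(
            perimeter=m[builder[1]], width=m[builder[2]], label=level,
            on_fallback=warn,
        )
    if kind == "pd":
        # the measured depth is the width of a stadium rotated through 90
        # degrees (the heels)
        return stadium_from_attributes(
            perimeter=m[builder[1]], width=m[builder[2]],
            orientation=ANTEROPOSTERIOR, label=level, on_fallback=warn,
        )
    if kind == "wd":
        return stadium_from_attributes(
            width=m[builder[1]], depth=m[builder[2]], label=level,
            on_fallback=warn,
        )
    if kind == "acromion":
        base = stadium_from_attributes(
            width=m["Ls4w"], depth=m["Ls4d"], label="Ls4", on_fallback=warn
        )
        r = scheme.ACROMION_RADIUS_RATIO * base.radius
        t = base.width / 2.0 - r
        return Stadium(r, t, MEDIOLATERAL, level)
    if kind == "hip":
        ls0 = stadium_from_attributes(
            perimeter=m["Ls0p"], width=m["Ls0w"], label="Ls0", on_fallback=warn
        )
        r = 0.5 * math.sqrt(ls0.radius * ls0.width)
        return Stadium(r, 0.0, MEDIOLATERAL, level)
    raise MeasurementError(f"unknown level builder {kind!r} for {level}")


def resolve_levels(m: MeasurementSet) -> SolidStackSpec:
    """Construct every level cross section and every solid spec from a
    measurement set.

    Per-solid heights come from differencing consecutive level positions;
    a non-positive difference means the cumulative length measurements are
    out of order and is reported as an error naming the offending pair.
    """
    warnings: list[str] = []

    def warn(msg: str) -> None:
        warnings.append(msg)
        log.warning(msg)

    stadia: dict[str, Stadium] = {}
    positions: dict[str, float] = {}
    for level in scheme.LEVELS:
        positions[level] = _level_position(level, m)
        st = _build_stadium(level, m, warn)
        if st is not None:
            stadia[level] = st

    solids: dict[str, SolidSpec] = {}
    for label, kind, bottom, top in scheme.SOLIDS:
        height = positions[top] - positions[bottom]
        if height <= 0:
            raise MeasurementError(
                f"solid {label}: level {top} is not above {bottom} "
                f"(check the corresponding length measurements)"
            )
        solids[label] = SolidSpec(
            label=label,
            kind=kind,
            bottom=stadia[bottom],
            top=stadia.get(top),
            height=height,
            density_label=label,
        )
    return SolidStackSpec(stadia, positions, solids, tuple(warnings))
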