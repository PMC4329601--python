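"""Report rendering: fixed-width text and numerically round-tripping JSON.

A report is a list of sections; each section carries a title and one set
of rigid-body properties with annotations saying what frame the numbers
are in and about which point the tensor is taken.  The JSON writer
serialises the symmetric tensor as its six unique entries with full
``repr`` precision, so ``parse(write(x))`` reproduces ``x`` exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .solids import RigidBodyProperties

__all__ = ["ReportSection", "write_report", "parse_json_report"]


@dataclass(frozen=True)
class ReportSection:
    title: str
    props: RigidBodyProperties
    about: str = "origin"  # reference point of the tensor
    frame: str = "global"
    notes: tuple[str, ...] = field(default_factory=tuple)


_TENSOR_KEYS = ("ixx", "iyy", "izz", "ixy", "ixz", "iyz")


def _tensor_entries(inertia: np.ndarray) -> dict[str, float]:
    return {
        "ixx": float(inertia[0, 0]),
        "iyy": float(inertia[1, 1]),
        "izz": float(inertia[2, 2]),
        "ixy": float(inertia[0, 1]),
        "ixz": float(inertia[0, 2]),
        "iyz": float(inertia[1, 2]),
    }


def _check_finite(section: ReportSection) -> None:
    values = [section.props.mass, *section.props.com.ravel(),
              *section.props.inertia.ravel()]
    if any(not math.isfinite(v) for v in values):
        raise ValueError(f"section {section.title!r} contains non-finite values")


def write_report(sections: list[ReportSection], fmt: str = "text") -> str:
    """Render sections as fixed-width text or JSON; refuses NaN/inf."""
    for section in sections:
        _check_finite(section)
    if fmt == "json":
        payload = []
        for s in sections:
            payload.append({
                "title": s.title,
                "frame": s.frame,
                "about": s.about,
                "mass_kg": s.props.mass,
                "com_m": [float(v) for v in s.props.com],
                "inertia_kgm2": _tensor_entries(s.props.inertia),
                "notes": list(s.notes),
            })
        return json.dumps(payload, indent=2) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")

    lines: list[str] = []
    for s in sections:
        lines.append(s.title)
        lines.append("-" * len(s.title))
        lines.append(f"frame: {s.frame}   tensor about: {s.about}")
        lines.append(f"mass     {s.props.mass:18.12f} kg")
        cx, cy, cz = s.props.com
        lines.append(
            f"com      [{cx:18.12f} {cy:18.12f} {cz:18.12f}] m"
        )
        lines.append("inertia (kg m^2)")
        for row in s.props.inertia:
            lines.append(
                "         [" + " ".join(f"{v:18.12f}" for v in row) + "]"
            )
        for note in s.notes:
            lines.append(f"note: {note}")
        lines.append("")
    return "\n".join(lines)


def parse_json_report(text: str) -> list[ReportSection]:
    """Inverse of the JSON writer (exact numeric round trip)."""
    sections = []
    for entry in json.loads(text):
        t = entry["inertia_kgm2"]
        inertia = np.array([
            [t["ixx"], t["ixy"], t["ixz"]],
            [t["ixy"], t["iyy"], t["iyz"]],
            [t["ixz"], t["iyz"], t["izz"]],
        ])
        sections.append(ReportSection(
            title=entry["title"],
            props=RigidBodyProperties(
                entry["mass_kg"], np.array(entry["com_m"]), inertia,
                entry["frame"],
            ),
            about=entry["about"],
            frame=entry["frame"],
            notes=tuple(entry.get("notes", ())),
        ))
    return sections
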