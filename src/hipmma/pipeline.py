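"""Per-muscle, per-angle instantaneous moment arms, lengths, strains and
size normalization, swept over the hip-extension range.

The pipeline follows the nearest-point construction: the muscle's line of
action is the straight segment joining the posed origin and insertion
centroids; the 3D instantaneous moment arm (MMA) is the distance from the
hip joint center to the nearest point on that segment; and because an
obliquely running muscle contributes to several rotation axes at once, the
moment arm is additionally projected onto the flexion--extension
(parasagittal) plane so that only the contribution to hip extension is
reported.

Three projection semantics are available (``projection=``):

``vector`` (default)
    Project the 3D moment-arm *vector* (joint center -> nearest point) onto
    the parasagittal plane and report its length.  The most literal reading
    of projecting a measured moment arm into the plane.
``inplane``
    Project the joint center and the whole line of action into the plane
    first, then take the 2D perpendicular distance.
``axis``
    The magnitude of the torque-per-unit-force scalar about the
    flexion--extension axis, ``((p - c) x u) . n``; for a hinge this equals
    the tendon-excursion moment arm ``|dL/dtheta|``.

All three coincide for planar configurations and none can exceed the 3D
moment arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    DegenerateGeometryError,
    nearest_point_on_segment,
    project_vector_onto_plane,
    unit,
)
from .model import (
    REFERENCE_ANGLE_DEG,
    LimbPose,
    MusculoskeletalModel,
    pose_model,
)

__all__ = [
    "StrainBand",
    "MMARecord",
    "CurveTable",
    "PROJECTION_METHODS",
    "DEFAULT_MASS_EXPONENT",
    "line_of_action",
    "instantaneous_mma",
    "muscle_length",
    "strain",
    "normalize_by_mass",
    "sweep",
    "summarize_relative_lengths",
]

PROJECTION_METHODS = ("vector", "inplane", "axis")

#: allometric exponent used to size-correct lengths and moment arms
#: (body mass to the power 0.33)
DEFAULT_MASS_EXPONENT = 0.33

#: default sweep of hip extension angles, degrees
DEFAULT_SWEEP = (20.0, 160.0, 10.0)

CURVE_COLUMNS = [
    "model",
    "muscle",
    "angle_deg",
    "mma_3d_mm",
    "mma_projected_mm",
    "mma_normalized",
    "length_mm",
    "strain_pct",
    "strain_class",
]


@dataclass(frozen=True)
class StrainBand:
    """The optimal band of the length--tension relationship, as percent of
    resting length.  Default 85--115%, bounds inclusive."""

    low_pct: float = 85.0
    high_pct: float = 115.0

    def __post_init__(self):
        if not (0.0 < self.low_pct < 100.0 < self.high_pct):
            raise ValueError(
                f"strain band must satisfy 0 < low < 100 < high, "
                f"got ({self.low_pct}, {self.high_pct})"
            )

    def classify(self, strain_pct: float) -> str:
        if strain_pct < self.low_pct:
            return "suboptimal_short"
        if strain_pct > self.high_pct:
            return "suboptimal_long"
        return "optimal"


@dataclass(frozen=True)
class MMARecord:
    """One (muscle, pose) measurement of the sweep."""

    model: str
    muscle: str
    angle_deg: float
    mma_3d_mm: float
    mma_projected_mm: float
    mma_normalized: float
    length_mm: float
    strain_pct: float
    strain_class: str


class CurveTable:
    """Ordered (muscle x angle) sweep results backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame, sweep_spec: Tuple[float, float, float]):
        missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"curve table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)[CURVE_COLUMNS]
        self.sweep_spec = tuple(float(x) for x in sweep_spec)

    @property
    def angles(self) -> np.ndarray:
        return np.array(sorted(self.frame["angle_deg"].unique()))

    @property
    def muscles(self) -> List[str]:
        return list(dict.fromkeys(self.frame["muscle"]))

    def records(self) -> List[MMARecord]:
        return [MMARecord(**row) for row in self.frame.to_dict("records")]

    def muscle_curve(self, muscle: str, column: str = "mma_projected_mm") -> pd.Series:
        sub = self.frame[self.frame["muscle"] == muscle].sort_values("angle_deg")
        if sub.empty:
            raise KeyError(f"no records for muscle {muscle!r}")
        return sub.set_index("angle_deg")[column]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CurveTable):
            return NotImplemented
        return self.sweep_spec == other.sweep_spec and self.frame.equals(other.frame)


def line_of_action(
    model: MusculoskeletalModel, muscle: str, pose: LimbPose
) -> Tuple[np.ndarray, np.ndarray]:
    """Posed origin and insertion centroids of ``muscle`` — the endpoints of
    its straight line of action."""
    m = model.muscle(muscle)
    posed = pose_model(model, pose)
    a, b = posed[m.name]
    if np.linalg.norm(b - a) < 1e-12:
        raise DegenerateGeometryError(
            f"muscle {muscle!r}: posed origin and insertion coincide"
        )
    return a, b


def instantaneous_mma(
    model: MusculoskeletalModel,
    muscle: str,
    pose: LimbPose,
    clamp: bool = True,
    projection: str = "vector",
) -> Tuple[float, float]:
    """The 3D instantaneous moment arm and its flexion--extension projection.

    ``mma_3d`` is the distance from the hip joint center to the nearest
    point on the muscle's line of action (segment by default; the infinite
    line with ``clamp=False``).  ``mma_projected`` depends on the selected
    projection method (see module docstring) and never exceeds ``mma_3d``.
    """
    if projection not in PROJECTION_METHODS:
        raise ValueError(
            f"projection must be one of {PROJECTION_METHODS}, got {projection!r}"
        )
    a, b = line_of_action(model, muscle, pose)
    c = model.hip.center
    n = model.hip.fe_axis
    p, mma_3d = nearest_point_on_segment(a, b, c, clamp=clamp)

    if projection == "vector":
        _, mma_proj = project_vector_onto_plane(p - c, n)
    elif projection == "inplane":
        pa, _ = project_vector_onto_plane(a - c, n)
        pb, _ = project_vector_onto_plane(b - c, n)
        if np.linalg.norm(pb - pa) < 1e-12:
            # line of action parallel to the axis: projects to a point
            mma_proj = float(np.linalg.norm(pa))
        else:
            _, mma_proj = nearest_point_on_segment(pa, pb, np.zeros(3), clamp=clamp)
    else:  # axis
        u = unit(b - a)
        mma_proj = abs(float(np.cross(p - c, u) @ n))
    return float(mma_3d), float(mma_proj)


def muscle_length(
    model: MusculoskeletalModel, muscle: str, pose: LimbPose
) -> float:
    """Straight-line (chord) muscle length at ``pose``, in mm."""
    a, b = line_of_action(model, muscle, pose)
    return float(np.linalg.norm(b - a))


def strain(
    length_mm: float,
    resting_length_mm: float,
    band: StrainBand = StrainBand(),
) -> Tuple[float, str]:
    """Muscle strain: instantaneous length over resting length, in percent,
    with its position relative to the optimal force-generation band."""
    if resting_length_mm <= 0:
        raise ValueError("resting length must be positive")
    if length_mm <= 0:
        raise ValueError("muscle length must be positive")
    # ratio first: at the reference pose length == resting length bitwise
    # and the strain must come out exactly 100
    pct = 100.0 * (length_mm / resting_length_mm)
    return pct, band.classify(pct)


def normalize_by_mass(
    value: float, body_mass: float, exponent: float = DEFAULT_MASS_EXPONENT
) -> float:
    """Size-correct a length-type quantity by dividing by mass**exponent."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    return value / body_mass**exponent


def sweep_angles(
    start: float = DEFAULT_SWEEP[0],
    stop: float = DEFAULT_SWEEP[1],
    step: float = DEFAULT_SWEEP[2],
) -> np.ndarray:
    if not (start < stop and step > 0):
        raise ValueError(f"invalid sweep spec ({start}, {stop}, {step})")
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def sweep(
    model: MusculoskeletalModel,
    start: float = DEFAULT_SWEEP[0],
    stop: float = DEFAULT_SWEEP[1],
    step: float = DEFAULT_SWEEP[2],
    clamp: bool = True,
    projection: str = "vector",
    band: StrainBand = StrainBand(),
    mass_exponent: float = DEFAULT_MASS_EXPONENT,
    muscles: Optional[Sequence[str]] = None,
) -> CurveTable:
    """Run the full pipeline over the hip-extension sweep.

    One :class:`MMARecord` per (muscle, angle); the default sweep covers
    20 deg (strongly crouched) to 160 deg (nearly fully extended) in 10 deg
    increments — 15 poses.  Normalized moment arms use the *projected*
    moment arm divided by body mass to the ``mass_exponent``.
    """
    angles = sweep_angles(start, stop, step)
    names = list(muscles) if muscles is not None else model.muscle_names()
    rows = []
    for name in names:
        m = model.muscle(name)
        for ang in angles:
            pose = LimbPose(float(ang))
            mma3, mmap = instantaneous_mma(
                model, name, pose, clamp=clamp, projection=projection
            )
            L = muscle_length(model, name, pose)
            pct, cls = strain(L, m.resting_length, band)
            rows.append(
                {
                    "model": model.name,
                    "muscle": name,
                    "angle_deg": float(ang),
                    "mma_3d_mm": mma3,
                    "mma_projected_mm": mmap,
                    "mma_normalized": normalize_by_mass(
                        mmap, model.body_mass, mass_exponent
                    ),
                    "length_mm": L,
                    "strain_pct": pct,
                    "strain_class": cls,
                }
            )
    return CurveTable(pd.DataFrame(rows, columns=CURVE_COLUMNS), (start, stop, step))


def summarize_relative_lengths(
    model: MusculoskeletalModel, mass_exponent: float = DEFAULT_MASS_EXPONENT
) -> pd.DataFrame:
    """Size-corrected lengths of the skeletal elements and the resting
    muscle lengths: each length divided by body mass**0.33."""
    rows = [
        {"model": model.name, "element": "femur", "length_mm": model.femur_length},
        {"model": model.name, "element": "pelvis", "length_mm": model.pelvis_length},
    ]
    for m in model.muscles:
        rows.append(
            {"model": model.name, "element": m.name, "length_mm": m.resting_length}
        )
    df = pd.DataFrame(rows)
    df["relative_length"] = [
        normalize_by_mass(v, model.body_mass, mass_exponent) for v in df["length_mm"]
    ]
    df["body_mass_g"] = model.body_mass
    return df
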