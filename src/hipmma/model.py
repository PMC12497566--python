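"""Musculoskeletal data model: bones, attachment sites, muscles, the hip
hinge, and rigid posing of the femur + shank assembly.

Standardised model frame
------------------------
All geometry is expressed in one Cartesian frame (millimetres):

* **x** — medio-lateral (the default flexion--extension axis),
* **y** — cranial (towards the head),
* **z** — ventral (towards the belly / ground in a crouched quadruped).

The hip is modelled as a hinge: the joint center is the center of a sphere
fitted to femoral-head surface samples, and the flexion--extension axis is a
model *input* (defaulting to +x for models built in the standardised
orientation).  The hip extension angle is measured between the femur long
axis and the cranial (+y) axis within the parasagittal plane; the reference
pose is defined as exactly 90 deg at hip and knee, and posing rotates all
femur-fixed and shank-fixed geometry rigidly by ``(angle - 90)`` deg about
the hinge, so the knee stays locked at 90 deg by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    Sphere,
    fit_sphere,
    rotate_about_axis,
    unit,
)

__all__ = [
    "BONE_NAMES",
    "SEGMENTS",
    "HIP_EXTENSORS",
    "REFERENCE_ANGLE_DEG",
    "SWEEP_RANGE_DEG",
    "Bone",
    "AttachmentSite",
    "Muscle",
    "HipJointModel",
    "LimbPose",
    "MusculoskeletalModel",
    "attachment_centroid",
    "build_hip_joint",
    "pose_model",
]

BONE_NAMES = ("pelvis", "femur", "tibia", "fibula")
SEGMENTS = ("pelvis-fixed", "femur-fixed", "shank-fixed")

#: the five hip extensors under study: two uniarticular gluteals and three
#: biarticular hamstrings
HIP_EXTENSORS = (
    "gluteus_medius",
    "gluteus_minimus",
    "biceps_femoris",
    "semimembranosus",
    "semitendinosus",
)

#: hip and knee angle defining the reference pose (and resting lengths)
REFERENCE_ANGLE_DEG = 90.0
#: standard hip-extension sweep limits, degrees
SWEEP_RANGE_DEG = (20.0, 160.0)


@dataclass
class Bone:
    """A bone surface: vertices (mm), optional triangle faces, and the rigid
    segment it belongs to during the hip sweep."""

    name: str
    vertices: np.ndarray
    segment: str
    faces: Optional[np.ndarray] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"bone {self.name!r}: vertices must be (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError(f"bone {self.name!r}: non-finite vertices")
        if self.segment not in SEGMENTS:
            raise ValueError(
                f"bone {self.name!r}: segment must be one of {SEGMENTS}, "
                f"got {self.segment!r}"
            )
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int)

    @property
    def max_caliper_length(self) -> float:
        """Maximum pairwise vertex distance (used as the effective bone
        length when no explicit length is supplied)."""
        v = self.vertices
        # convex-hull-free O(n^2) is fine at the vertex counts used here,
        # but subsample defensively for very dense meshes
        if len(v) > 2000:
            rng = np.random.default_rng(0)
            v = v[rng.choice(len(v), 2000, replace=False)]
        d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))


@dataclass
class AttachmentSite:
    """A muscle attachment: a patch of surface points on one bone.

    The site's working coordinate is the *centroid*, the unweighted mean of
    the patch points; a single-point patch represents an explicitly placed
    centroid.
    """

    bone: Bone
    patch: np.ndarray

    def __post_init__(self):
        self.patch = np.atleast_2d(np.asarray(self.patch, dtype=float))
        if self.patch.size == 0:
            raise ValueError("attachment patch must be non-empty")
        if self.patch.shape[1] != 3:
            raise ValueError("attachment patch must be (n, 3)")

    @property
    def centroid(self) -> np.ndarray:
        return self.patch.mean(axis=0)


def attachment_centroid(site: AttachmentSite) -> np.ndarray:
    """Arithmetic mean of the patch points (mm)."""
    return site.centroid


@dataclass
class Muscle:
    """A straight-line muscle from a pelvic origin to a femoral or shank
    insertion.  ``resting_length`` is derived once, at the reference pose."""

    name: str
    origin: AttachmentSite
    insertion: AttachmentSite
    biarticular: bool
    resting_length: float = field(init=False, default=0.0)

    def __post_init__(self):
        if self.origin.bone.segment != "pelvis-fixed":
            raise ValueError(f"muscle {self.name!r}: origin must lie on the pelvis")
        on_shank = self.insertion.bone.segment == "shank-fixed"
        if self.biarticular != on_shank:
            raise ValueError(
                f"muscle {self.name!r}: biarticular flag ({self.biarticular}) "
                f"inconsistent with insertion segment "
                f"({self.insertion.bone.segment!r})"
            )
        L0 = float(np.linalg.norm(self.origin.centroid - self.insertion.centroid))
        if L0 <= 0:
            raise DegenerateGeometryError(
                f"muscle {self.name!r}: origin and insertion centroids coincide"
            )
        self.resting_length = L0


@dataclass
class HipJointModel:
    """The hip hinge: fitted sphere center, flexion--extension axis, and the
    femur long-axis direction at the reference pose."""

    center: np.ndarray
    fe_axis: np.ndarray
    zero_pose_femur_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    sphere: Optional[Sphere] = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.fe_axis = unit(self.fe_axis)
        self.zero_pose_femur_axis = unit(self.zero_pose_femur_axis)


def build_hip_joint(
    femoral_head_points,
    fe_axis=(1.0, 0.0, 0.0),
    reference_femur_axis=(0.0, 0.0, 1.0),
) -> HipJointModel:
    """Estimate the hip joint center by sphere-fitting femoral-head surface
    samples and assemble the hinge model around it."""
    sph = fit_sphere(femoral_head_points)
    return HipJointModel(
        center=sph.center,
        fe_axis=fe_axis,
        zero_pose_femur_axis=reference_femur_axis,
        sphere=sph,
    )


@dataclass(frozen=True)
class LimbPose:
    """One frame of the sweep: a hip extension angle with the knee locked.

    ``hip_extension_deg`` follows the convention reference = 90 (small =
    crouched, large = extended); the knee is always 90 deg relative to the
    femur, which is why it has no free field.
    """

    hip_extension_deg: float
    knee_deg: float = 90.0

    def __post_init__(self):
        if self.knee_deg != 90.0:
            raise ValueError("the knee is locked at 90 deg in this model")
        lo, hi = SWEEP_RANGE_DEG
        if not (lo <= self.hip_extension_deg <= hi):
            warnings.warn(
                f"hip extension angle {self.hip_extension_deg} deg is outside "
                f"the standard [{lo:.0f}, {hi:.0f}] deg sweep range",
                stacklevel=3,
            )


@dataclass
class MusculoskeletalModel:
    """The static anatomy: bones, muscles, hip hinge, body mass and the
    effective pelvis/femur lengths used for size summaries."""

    name: str
    bones: Dict[str, Bone]
    muscles: List[Muscle]
    hip: HipJointModel
    body_mass: float  # grams
    pelvis_length: float = 0.0  # mm; 0 -> derived from the pelvis mesh
    femur_length: float = 0.0

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        names = list(self.bones)
        if len(set(names)) != len(names):
            raise ValueError("bone names must be unique")
        if self.pelvis_length <= 0:
            if "pelvis" not in self.bones:
                raise ValueError("pelvis_length missing and no pelvis bone given")
            self.pelvis_length = self.bones["pelvis"].max_caliper_length
        if self.femur_length <= 0:
            if "femur" not in self.bones:
                raise ValueError("femur_length missing and no femur bone given")
            self.femur_length = self.bones["femur"].max_caliper_length

    def muscle(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle named {name!r} in model {self.name!r}")

    def muscle_names(self) -> List[str]:
        return [m.name for m in self.muscles]


def _pose_points(
    model: MusculoskeletalModel, points: np.ndarray, segment: str, pose: LimbPose
) -> np.ndarray:
    """Rigidly pose a stack of points belonging to ``segment``."""
    if segment == "pelvis-fixed":
        return np.array(points, dtype=float)
    delta = pose.hip_extension_deg - REFERENCE_ANGLE_DEG
    return rotate_about_axis(points, model.hip.center, model.hip.fe_axis, delta)


def pose_model(
    model: MusculoskeletalModel, pose: LimbPose
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Return the posed origin and insertion centroid of every muscle.

    Pelvis-fixed points are unchanged; femur-fixed and shank-fixed points
    rotate together about ``(hip.center, hip.fe_axis)`` by
    ``hip_extension_deg - 90`` degrees, keeping the knee at 90 deg by
    construction.  Posing is a pure function of ``(model, pose)``.
    """
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for m in model.muscles:
        o = _pose_points(
            model, m.origin.centroid, m.origin.bone.segment, pose
        )
        i = _pose_points(
            model, m.insertion.centroid, m.insertion.bone.segment, pose
        )
        out[m.name] = (o, i)
    return out
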