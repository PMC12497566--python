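"""Robustness analyses for the moment-arm pipeline.

Three perturbation families mirror how a manual model-building workflow can
go wrong:

* **placement_jitter** — repeated manual placement of attachment centroids:
  each replicate displaces every centroid by an isotropic Gaussian offset
  and re-projects it onto the bone surface (or the attachment patch when no
  surface is available), then reruns the sweep;
* **mass_fraction** — uncertainty in the body-mass measurement: the sweep
  is recomputed with mass scaled by (1 + f); raw moment arms are unchanged
  and normalized values scale by the analytic factor (1 + f)**-exponent;
* **origin_shift** — uncertainty in one muscle's origin: the origin
  centroid is translated along the pelvis principal axis by a fraction of
  pelvic length, snapped back to the pelvis surface, and the sweep rerun.

Reports carry per-(muscle, angle) mean / sd / min / max across replicates
or levels and are bit-reproducible given (model, spec, seed).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import closest_point_on_triangles
from .model import AttachmentSite, Bone, MusculoskeletalModel, Muscle
from .pipeline import (
    DEFAULT_MASS_EXPONENT,
    DEFAULT_SWEEP,
    CurveTable,
    StrainBand,
    sweep,
)

__all__ = [
    "PerturbationSpec",
    "SensitivityReport",
    "DEFAULT_FRACTIONS",
    "placement_repeatability",
    "mass_perturbation",
    "origin_shift",
]

#: the four discrete perturbation levels used for mass and origin shifts
DEFAULT_FRACTIONS = (-0.20, -0.10, 0.10, 0.20)

#: quantities whose dispersion the reports summarise
_QUANTITIES = ["mma_3d_mm", "mma_projected_mm", "mma_normalized",
               "length_mm", "strain_pct"]


@dataclass(frozen=True)
class PerturbationSpec:
    """What was perturbed, by how much, and with what replication."""

    kind: str  # placement_jitter | mass_fraction | origin_shift
    magnitude: Tuple[float, ...]  # sigma (mm) or fraction levels
    replicates: int
    seed: int
    muscle: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("placement_jitter", "mass_fraction", "origin_shift"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SensitivityReport:
    """Per-(muscle, angle, quantity) dispersion across replicates/levels."""

    spec: PerturbationSpec
    #: long-format per-replicate sweep results with a 'level' column
    replicates: pd.DataFrame
    #: aggregated mean/sd/min/max
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        long = self.replicates.melt(
            id_vars=["level", "model", "muscle", "angle_deg"],
            value_vars=_QUANTITIES,
            var_name="quantity",
        )
        g = long.groupby(["muscle", "angle_deg", "quantity"], sort=True)["value"]
        self.summary = (
            g.agg(mean="mean", sd="std", min="min", max="max")
            .reset_index()
        )
        # a single replicate has zero dispersion, not NaN
        self.summary["sd"] = self.summary["sd"].fillna(0.0)
        self.summary.insert(0, "kind", self.spec.kind)

    def quantity(self, quantity: str) -> pd.DataFrame:
        return self.summary[self.summary["quantity"] == quantity]


def _as_frame(table: CurveTable, level) -> pd.DataFrame:
    df = table.frame.copy()
    df.insert(0, "level", level)
    return df


def _surface_snapper(bone: Bone):
    """Return a function projecting points onto the bone surface.

    Uses exact closest-point queries on the triangulated surface when faces
    are available; otherwise falls back to the nearest patch/cloud vertex.
    """
    if bone.faces is not None and len(bone.faces):
        triangles = bone.vertices[bone.faces]

        def snap(p: np.ndarray) -> np.ndarray:
            point, _ = closest_point_on_triangles(triangles, p)
            return point

    else:
        verts = bone.vertices

        def snap(p: np.ndarray) -> np.ndarray:
            return verts[np.argmin(np.sum((verts - p) ** 2, axis=1))]

    return snap


def _with_site(model: MusculoskeletalModel, muscle_name: str, end: str,
               new_point: np.ndarray) -> MusculoskeletalModel:
    """A copy of ``model`` with one attachment replaced by a single-point
    patch at ``new_point`` (resting length re-derived)."""
    m2 = copy.copy(model)
    m2.muscles = list(model.muscles)
    for k, m in enumerate(m2.muscles):
        if m.name != muscle_name:
            continue
        origin, insertion = m.origin, m.insertion
        site = AttachmentSite(
            bone=getattr(m, end).bone, patch=new_point.reshape(1, 3)
        )
        if end == "origin":
            origin = site
        else:
            insertion = site
        m2.muscles[k] = Muscle(
            name=m.name, origin=origin, insertion=insertion,
            biarticular=m.biarticular,
        )
    return m2


def placement_repeatability(
    model: MusculoskeletalModel,
    sigma_mm: float = 0.5,
    replicates: int = 5,
    seed: int = 0,
    sweep_spec: Tuple[float, float, float] = DEFAULT_SWEEP,
    **sweep_kwargs,
) -> SensitivityReport:
    """Repeated attachment-centroid placement.

    Each replicate displaces every origin and insertion centroid by an
    isotropic Gaussian offset (sd ``sigma_mm``) and re-projects the result
    onto the bone surface, emulating independent manual placements; the
    full sweep is then recomputed.  ``sigma_mm = 0`` leaves the model
    untouched, so all dispersion statistics are exactly zero.
    Deterministic given ``seed``.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    spec = PerturbationSpec(
        kind="placement_jitter", magnitude=(sigma_mm,),
        replicates=replicates, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    snappers = {name: _surface_snapper(b) for name, b in model.bones.items()}
    frames = []
    for rep in range(replicates):
        m2 = model
        if sigma_mm > 0:
            for m in model.muscles:
                for end in ("origin", "insertion"):
                    site = getattr(m, end)
                    jittered = site.centroid + rng.normal(0.0, sigma_mm, 3)
                    snapped = snappers[site.bone.name](jittered)
                    m2 = _with_site(m2, m.name, end, snapped)
        table = sweep(m2, *sweep_spec, **sweep_kwargs)
        frames.append(_as_frame(table, rep))
    return SensitivityReport(spec, pd.concat(frames, ignore_index=True))


def mass_perturbation(
    model: MusculoskeletalModel,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    sweep_spec: Tuple[float, float, float] = DEFAULT_SWEEP,
    **sweep_kwargs,
) -> SensitivityReport:
    """Recompute the sweep with body mass scaled by (1 + f) per level.

    Geometry is untouched, so raw moment arms, lengths and strains are
    identical across levels; only the size-normalized values change, by the
    analytic factor (1 + f)**-exponent.
    """
    for f in fractions:
        if f <= -1.0:
            raise ValueError(f"mass fraction {f} would make mass non-positive")
    spec = PerturbationSpec(
        kind="mass_fraction", magnitude=tuple(fractions), replicates=1, seed=0,
    )
    frames = []
    for f in fractions:
        m2 = copy.copy(model)
        m2.body_mass = model.body_mass * (1.0 + f)
        frames.append(_as_frame(sweep(m2, *sweep_spec, **sweep_kwargs), f))
    return SensitivityReport(spec, pd.concat(frames, ignore_index=True))


def pelvis_principal_axis(model: MusculoskeletalModel) -> np.ndarray:
    """Longest principal component of the pelvis vertex cloud, oriented
    cranially (positive dot with the +y model axis)."""
    if "pelvis" not in model.bones:
        raise ValueError("model has no pelvis bone")
    V = model.bones["pelvis"].vertices
    Vc = V - V.mean(axis=0)
    _, _, vt = np.linalg.svd(Vc, full_matrices=False)
    axis = vt[0]
    if axis[1] < 0:
        axis = -axis
    return axis


def origin_shift(
    model: MusculoskeletalModel,
    muscle: str = "biceps_femoris",
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    sweep_spec: Tuple[float, float, float] = DEFAULT_SWEEP,
    include_baseline: bool = True,
    **sweep_kwargs,
) -> SensitivityReport:
    """Shift one muscle's origin along the pelvis long axis.

    Per level the origin centroid is translated by ``f * pelvis_length``
    along the pelvis principal axis (cranially for positive ``f``), snapped
    back to the nearest pelvis surface point, and the sweep recomputed for
    that muscle.
    """
    mus = model.muscle(muscle)  # raises KeyError if absent
    if model.pelvis_length <= 0:
        raise ValueError("pelvis_length must be positive")
    spec = PerturbationSpec(
        kind="origin_shift", magnitude=tuple(fractions), replicates=1,
        seed=0, muscle=muscle,
    )
    axis = pelvis_principal_axis(model)
    snap = _surface_snapper(mus.origin.bone)
    bounds = (
        mus.origin.bone.vertices.min(axis=0),
        mus.origin.bone.vertices.max(axis=0),
    )
    levels = ([0.0] if include_baseline else []) + [f for f in fractions if f != 0.0]
    frames = []
    for f in levels:
        if f == 0.0:
            m2 = model
        else:
            shifted = mus.origin.centroid + f * model.pelvis_length * axis
            if np.any(shifted < bounds[0]) or np.any(shifted > bounds[1]):
                warnings.warn(
                    f"origin_shift f={f:+.2f}: shifted point leaves the pelvis "
                    "bounding volume; snapping to the surface anyway",
                    stacklevel=2,
                )
            m2 = _with_site(model, muscle, "origin", snap(shifted))
        table = sweep(m2, *sweep_spec, muscles=[muscle], **sweep_kwargs)
        frames.append(_as_frame(table, f))
    return SensitivityReport(spec, pd.concat(frames, ignore_index=True))
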