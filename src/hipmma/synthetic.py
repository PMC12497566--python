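"""Parametric synthetic hindlimb models with known ground truth.

The generator emulates the geometry a segmented micro-CT hindlimb provides
to the pipeline: a pelvis + femur + tibia/fibula assembly in the
standardised model frame (x medio-lateral, y cranial, z ventral; hip joint
center at the origin), femoral-head surface samples on a sphere of known
center and radius, and attachment layouts for the five hip extensors — two
uniarticular gluteals from the iliac wing to the proximal femur
(trochanteric region) and three biarticular hamstrings from the caudal
pelvis to the tibia.

Bones are simple analytic solids (an elongated ellipsoid pelvis and capped
cylinder long bones) rather than realistic meshes: the pipeline consumes
only surfaces, attachment patches, and head samples, and analytic solids
admit exact oracles.  Each attachment site is realised as a small
"tuberosity" fan of mesh vertices arranged symmetrically around the
designed attachment point, so the patch centroid reproduces the designed
coordinate exactly and noise-free geometry is exactly recoverable.

Morphotype presets encode, as generator parameters, the qualitative
contrast between trunk-to-trunk leapers (attachments placed farther from
the joint center: longer moment arms, favouring torque) and horizontal
leapers (attachments closer in: shorter moment arms, favouring rotational
velocity).  They are illustrative placements, not inferred anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh

from .geometry import rotation_about_axis_matrix

__all__ = [
    "SyntheticModelSpec",
    "GroundTruth",
    "MORPHOTYPES",
    "generate_model",
    "generate_cohort",
    "cohort_specs",
]

#: multiplier applied to attachment offsets (trochanteric radius, ischial
#: reach) per morphotype; larger offsets -> longer moment arms
MORPHOTYPES = {
    "trunk_leaper": 1.25,
    "generic": 1.0,
    "horizontal_leaper": 0.8,
}

#: default masses (g) spanning the callitrichid range (roughly 120-700 g)
COHORT_MASSES = (480.0, 350.0, 450.0, 620.0)
COHORT_MORPHOTYPES = ("trunk_leaper", "horizontal_leaper", "generic", "horizontal_leaper")


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Parameters of one synthetic hindlimb model.

    Lengths are mm, mass is grams.  ``planar=True`` places every attachment
    centroid in the parasagittal plane (x = 0), which makes the closed-form
    per-angle moment arm of :class:`GroundTruth` exact.
    ``attachment_jitter`` adds a seeded uniform offset (mm) to every
    designed attachment coordinate, for generating families of random
    layouts; 0 gives the canonical anatomy.
    """

    seed: int = 0
    name: str = "synthetic"
    body_mass: float = 450.0
    pelvis_length: float = 30.0
    femur_length: float = 35.0
    tibia_length: float = 38.0
    head_radius: float = 3.5
    head_sample_n: int = 200
    head_noise_sigma: float = 0.0
    morphotype: str = "generic"
    planar: bool = False
    attachment_mode: str = "patch"  # "patch" | "centroid"
    patch_radius: float = 1.0
    patch_points: int = 8
    attachment_jitter: float = 0.0
    semitendinosus_insertion_frac: float = 0.37

    def __post_init__(self):
        for f in ("body_mass", "pelvis_length", "femur_length", "tibia_length",
                  "head_radius", "patch_radius"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.head_sample_n < 4:
            raise ValueError("head_sample_n must be >= 4")
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(
                f"morphotype must be one of {sorted(MORPHOTYPES)}, "
                f"got {self.morphotype!r}"
            )
        if self.attachment_mode not in ("patch", "centroid"):
            raise ValueError("attachment_mode must be 'patch' or 'centroid'")
        if self.patch_radius >= min(self.pelvis_length, self.femur_length) / 4:
            raise ValueError("patch_radius too large for the bone dimensions")


@dataclass
class GroundTruth:
    """What the generator knows exactly about a model it emitted."""

    hip_center: np.ndarray
    head_radius: float
    fe_axis: np.ndarray
    planar: bool
    #: reference-pose attachment centroids: muscle -> (origin, insertion)
    attachments: Dict[str, Tuple[np.ndarray, np.ndarray]]
    #: muscles whose insertion rotates with the femur/shank assembly
    mobile_insertions: Tuple[str, ...]

    def posed_attachments(self, muscle: str, angle_deg: float):
        """Reference attachments rigidly posed to ``angle_deg`` (hinge
        rotation by angle - 90 about the flexion-extension axis)."""
        o, i = self.attachments[muscle]
        R = rotation_about_axis_matrix(self.fe_axis, angle_deg - 90.0)
        c = self.hip_center
        return o.copy(), c + R @ (i - c)

    def closed_form_mma(self, muscle: str, angle_deg: float) -> float:
        """Closed-form perpendicular distance from the hip center to the
        infinite line of action at ``angle_deg`` (|AQ x d| / |d|).

        Exact for any layout; coincides with the pipeline's planar-projected
        values only when the layout is planar.
        """
        o, i = self.posed_attachments(muscle, angle_deg)
        d = i - o
        return float(np.linalg.norm(np.cross(self.hip_center - o, d))
                     / np.linalg.norm(d))

    def to_jsonable(self) -> dict:
        return {
            "hip_center": self.hip_center.tolist(),
            "head_radius": self.head_radius,
            "fe_axis": self.fe_axis.tolist(),
            "planar": self.planar,
            "attachments": {
                k: {"origin": o.tolist(), "insertion": i.tolist()}
                for k, (o, i) in self.attachments.items()
            },
            "mobile_insertions": list(self.mobile_insertions),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroundTruth":
        return cls(
            hip_center=np.array(d["hip_center"], dtype=float),
            head_radius=float(d["head_radius"]),
            fe_axis=np.array(d["fe_axis"], dtype=float),
            planar=bool(d["planar"]),
            attachments={
                k: (np.array(v["origin"], float), np.array(v["insertion"], float))
                for k, v in d["attachments"].items()
            },
            mobile_insertions=tuple(d["mobile_insertions"]),
        )


def _attachment_layout(spec: SyntheticModelSpec) -> Dict[str, dict]:
    """Designed attachment coordinates at the reference pose (hip at origin).

    Gluteal insertions sit on a trochanteric offset that, at the reference
    pose, points dorso-caudally from the joint center; hamstring origins sit
    on the caudal (ischial) pelvis, their insertions along the tibia, which
    at the reference pose runs caudally from the knee at (0, 0, femur
    length).
    """
    P, F, T = spec.pelvis_length, spec.femur_length, spec.tibia_length
    g = MORPHOTYPES[spec.morphotype]

    def troch(radius, beta_deg, x):
        # trochanteric offset: at the reference pose it points dorso-caudally
        # (beta measured from the cranial axis, positive towards ventral)
        b = np.deg2rad(beta_deg)
        return np.array([x, radius * np.cos(b), radius * np.sin(b)])

    knee = np.array([0.0, 0.0, F])
    caudal = np.array([0.0, -1.0, 0.0])  # tibia direction at reference

    # Gluteal origins sit on the lateral iliac face at the same lateral
    # offset as the trochanteric insertion: the muscle then runs in a
    # lateral parasagittal plane, and its projected moment arm rises
    # monotonically with extension into the trochanteric plateau.  Hamstring
    # (ischial) origins sit well medial of the lateral hip joint; that
    # medio-lateral offset is what keeps the nearest point interior to the
    # line of action over most of the sweep and shapes the projected moment
    # arm into a bell with an interior maximum.
    layout = {
        "gluteus_medius": {
            "origin": np.array([3.5, 0.60 * P, -5.0]),
            "insertion": troch(2.2 * g, -107.0, 3.5),
            "insertion_bone": "femur",
        },
        "gluteus_minimus": {
            "origin": np.array([3.0, 0.50 * P, -3.5]),
            "insertion": troch(1.6 * g, -110.0, 3.0),
            "insertion_bone": "femur",
        },
        "biceps_femoris": {
            "origin": np.array([-12.0, -0.2333 * P * g, -4.0]),
            "insertion": knee + 0.15 * T * caudal + np.array([1.0, 0.0, 0.0]),
            "insertion_bone": "tibia",
        },
        "semimembranosus": {
            "origin": np.array([-11.0, -0.20 * P * g, -3.0]),
            "insertion": knee + 0.10 * T * caudal + np.array([-1.0, 0.0, 0.0]),
            "insertion_bone": "tibia",
        },
        "semitendinosus": {
            "origin": np.array([-13.0, -0.2667 * P * g, -4.0]),
            "insertion": knee
            + spec.semitendinosus_insertion_frac * T * caudal,
            "insertion_bone": "tibia",
        },
    }

    if spec.attachment_jitter > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
        for entry in layout.values():
            entry["origin"] = entry["origin"] + rng.uniform(
                -spec.attachment_jitter, spec.attachment_jitter, 3
            )
            entry["insertion"] = entry["insertion"] + rng.uniform(
                -spec.attachment_jitter, spec.attachment_jitter, 3
            )

    if spec.planar:
        for entry in layout.values():
            entry["origin"] = entry["origin"] * np.array([0.0, 1.0, 1.0])
            entry["insertion"] = entry["insertion"] * np.array([0.0, 1.0, 1.0])

    for name, entry in layout.items():
        entry["origin_bone"] = "pelvis"
        entry["biarticular"] = entry["insertion_bone"] == "tibia"
    return layout


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere sampling."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _tuberosity_fan(center: np.ndarray, radius: float, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """A small symmetric vertex fan around ``center``.

    ``k`` ring vertices on a circle of ``radius`` plus the center vertex;
    the vertex mean equals ``center`` exactly.  Faces triangulate the fan so
    the vertices survive OBJ round trips that drop unreferenced vertices.
    """
    # fixed in-plane basis; the fan orientation is cosmetic
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, np.cos(np.pi / 7), np.sin(np.pi / 7)])
    ang = 2.0 * np.pi * np.arange(k) / k
    ring = center + radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    verts = np.vstack([center, ring])
    faces = np.array([[0, 1 + j, 1 + (j + 1) % k] for j in range(k)])
    return verts, faces


def _ellipsoid(center, semiaxes, subdivisions=3) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = m.vertices * np.asarray(semiaxes) + np.asarray(center)
    return trimesh.Trimesh(vertices=v, faces=m.faces, process=False)


def _capped_cylinder(p0, p1, radius, sections=24) -> trimesh.Trimesh:
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    h = float(np.linalg.norm(p1 - p0))
    m = trimesh.creation.cylinder(radius=radius, height=h, sections=sections)
    # align +z of the canonical cylinder with p1 - p0, center at midpoint
    T = trimesh.geometry.align_vectors([0, 0, 1], (p1 - p0) / h)
    v = m.vertices @ np.asarray(T)[:3, :3].T + (p0 + p1) / 2.0
    return trimesh.Trimesh(vertices=v, faces=m.faces, process=False)


def _append_fans(mesh: trimesh.Trimesh, points, radius, k):
    """Append tuberosity fans at ``points``; return (mesh, index lists)."""
    verts = [np.asarray(mesh.vertices)]
    faces = [np.asarray(mesh.faces)]
    offset = len(mesh.vertices)
    index_lists = []
    for p in points:
        fv, ff = _tuberosity_fan(np.asarray(p, float), radius, k)
        index_lists.append(list(range(offset, offset + len(fv))))
        faces.append(ff + offset)
        verts.append(fv)
        offset += len(fv)
    out = trimesh.Trimesh(
        vertices=np.vstack(verts), faces=np.vstack(faces), process=False
    )
    return out, index_lists


def generate_model(
    spec: SyntheticModelSpec, out_dir
) -> Tuple[Path, GroundTruth]:
    """Write a synthetic model (OBJ meshes + JSON descriptor + ground truth)
    to ``out_dir`` and return the descriptor path and the ground truth.

    Deterministic given the spec (including its seed): identical specs yield
    byte-identical descriptors and ground-truth files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec_layout = _attachment_layout(spec)
    P, F, T = spec.pelvis_length, spec.femur_length, spec.tibia_length

    # --- bones -----------------------------------------------------------
    pelvis = _ellipsoid(
        center=[-4.75, 0.17 * P, -3.0], semiaxes=[9.5, P / 2.0, 6.5]
    )
    femur = trimesh.util.concatenate(
        _capped_cylinder([0, 0, 0.5 * spec.head_radius], [0, 0, F], radius=1.8),
        _ellipsoid([0.0, 0.0, 0.0], [spec.head_radius] * 3, subdivisions=2),
    )
    femur = trimesh.Trimesh(vertices=femur.vertices, faces=femur.faces, process=False)
    knee = np.array([0.0, 0.0, F])
    tibia = _capped_cylinder(knee, knee + np.array([0.0, -T, 0.0]), radius=1.5)
    fibula = _capped_cylinder(
        knee + np.array([1.8, -2.0, 1.0]),
        knee + np.array([1.8, -0.85 * T, 1.0]),
        radius=0.6,
    )

    # --- attachment tuberosities ----------------------------------------
    bone_points: Dict[str, List[np.ndarray]] = {"pelvis": [], "femur": [], "tibia": []}
    keys: Dict[str, List[Tuple[str, str]]] = {"pelvis": [], "femur": [], "tibia": []}
    for mname, entry in spec_layout.items():
        bone_points["pelvis"].append(entry["origin"])
        keys["pelvis"].append((mname, "origin"))
        bone_points[entry["insertion_bone"]].append(entry["insertion"])
        keys[entry["insertion_bone"]].append((mname, "insertion"))

    meshes = {"pelvis": pelvis, "femur": femur, "tibia": tibia, "fibula": fibula}
    patch_indices: Dict[Tuple[str, str], Tuple[str, List[int]]] = {}
    for bone_name in ("pelvis", "femur", "tibia"):
        mesh, idx_lists = _append_fans(
            meshes[bone_name],
            bone_points[bone_name],
            spec.patch_radius,
            spec.patch_points,
        )
        meshes[bone_name] = mesh
        for key, idx in zip(keys[bone_name], idx_lists):
            patch_indices[key] = (bone_name, idx)

    mesh_files = {}
    for bone_name, mesh in meshes.items():
        fname = f"{bone_name}.obj"
        # full-precision export: attachment centroids must survive the OBJ
        # round trip exactly
        mesh.export(out / fname, include_normals=False, digits=17)
        mesh_files[bone_name] = fname

    # --- femoral head samples -------------------------------------------
    head = spec.head_radius * _fibonacci_sphere(spec.head_sample_n)
    if spec.head_noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
        head = head + rng.normal(0.0, spec.head_noise_sigma, head.shape)

    # --- descriptor ------------------------------------------------------
    segments = {
        "pelvis": "pelvis-fixed",
        "femur": "femur-fixed",
        "tibia": "shank-fixed",
        "fibula": "shank-fixed",
    }
    muscles_json = []
    for mname, entry in spec_layout.items():
        if spec.attachment_mode == "patch":
            ob, oi = patch_indices[(mname, "origin")]
            ib, ii = patch_indices[(mname, "insertion")]
            origin_json = {"bone": ob, "vertex_indices": oi}
            insertion_json = {"bone": ib, "vertex_indices": ii}
        else:
            origin_json = {"bone": "pelvis", "centroid": entry["origin"].tolist()}
            insertion_json = {
                "bone": entry["insertion_bone"],
                "centroid": entry["insertion"].tolist(),
            }
        muscles_json.append(
            {
                "name": mname,
                "origin": origin_json,
                "insertion": insertion_json,
                "biarticular": entry["biarticular"],
            }
        )

    descriptor = {
        "name": spec.name,
        "body_mass_g": spec.body_mass,
        "pelvis_length_mm": P,
        "femur_length_mm": F,
        "fe_axis": [1.0, 0.0, 0.0],
        "reference_femur_axis": [0.0, 0.0, 1.0],
        "bones": [
            {"name": b, "segment": segments[b], "mesh": mesh_files[b]}
            for b in ("pelvis", "femur", "tibia", "fibula")
        ],
        "femoral_head": {"points": head.tolist()},
        "muscles": muscles_json,
    }
    descriptor_path = out / "model.json"
    descriptor_path.write_text(json.dumps(descriptor, indent=1, sort_keys=True))

    truth = GroundTruth(
        hip_center=np.zeros(3),
        head_radius=spec.head_radius,
        fe_axis=np.array([1.0, 0.0, 0.0]),
        planar=spec.planar,
        attachments={
            m: (entry["origin"].copy(), entry["insertion"].copy())
            for m, entry in spec_layout.items()
        },
        mobile_insertions=tuple(spec_layout),
    )
    (out / "ground_truth.json").write_text(
        json.dumps(truth.to_jsonable(), indent=1, sort_keys=True)
    )
    return descriptor_path, truth


def cohort_specs(
    n_models: int = 4,
    base_spec: Optional[SyntheticModelSpec] = None,
    masses=COHORT_MASSES,
    morphotypes=COHORT_MORPHOTYPES,
) -> List[SyntheticModelSpec]:
    """Specs for a comparative cohort differing in morphotype and mass."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    base = base_spec or SyntheticModelSpec()
    specs = []
    for k in range(n_models):
        morph = morphotypes[k % len(morphotypes)]
        specs.append(
            replace(
                base,
                seed=base.seed + k,
                name=f"model_{k:02d}_{morph}",
                morphotype=morph,
                body_mass=float(masses[k % len(masses)]),
            )
        )
    return specs


def generate_cohort(
    n_models: int, out_dir, base_spec: Optional[SyntheticModelSpec] = None
) -> List[Tuple[Path, GroundTruth]]:
    """Generate ``n_models`` models into subdirectories of ``out_dir``."""
    out = Path(out_dir)
    results = []
    for spec in cohort_specs(n_models, base_spec):
        results.append(generate_model(spec, out / spec.name))
    return results
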