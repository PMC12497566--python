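"""Model-descriptor reading, schema validation, and tabular output I/O.

The model descriptor is a JSON document tying together bone meshes
(OBJ/PLY/STL, read via ``trimesh``), per-muscle attachment patches (bone
name + 0-based vertex indices, or explicit centroid coordinates), the
femoral-head specification (surface sample points, mesh vertex indices, or
an explicit sphere), the flexion--extension axis, body mass and effective
bone lengths.  ``docs/model_schema.md`` in the repository documents every
field; :data:`DESCRIPTOR_SCHEMA` carries the same structure machine-readably.

Tabular outputs are CSV with a ``#``-prefixed provenance header (tool
version, config hash, seed, fitted sphere) so a producing command can be
re-run exactly; repeated runs with equal configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .geometry import Sphere, fit_sphere
from .model import (
    SEGMENTS,
    AttachmentSite,
    Bone,
    HipJointModel,
    Muscle,
    MusculoskeletalModel,
)
from .pipeline import CURVE_COLUMNS, CurveTable

__all__ = [
    "SchemaError",
    "DESCRIPTOR_SCHEMA",
    "read_model",
    "write_curves",
    "read_curves",
    "write_table",
    "config_hash",
]


class SchemaError(ValueError):
    """A model descriptor violated the schema; the message names the
    offending field."""


#: minimal machine-readable descriptor schema (JSON-Schema-like subset)
DESCRIPTOR_SCHEMA = {
    "type": "object",
    "required": ["name", "body_mass_g", "fe_axis", "bones", "femoral_head", "muscles"],
    "properties": {
        "name": {"type": "string"},
        "body_mass_g": {"type": "number", "exclusiveMinimum": 0},
        "pelvis_length_mm": {"type": "number", "exclusiveMinimum": 0},
        "femur_length_mm": {"type": "number", "exclusiveMinimum": 0},
        "fe_axis": {"type": "array", "items": {"type": "number"}, "length": 3},
        "reference_femur_axis": {"type": "array", "length": 3},
        "bones": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["name", "segment"],
                "properties": {
                    "name": {"type": "string"},
                    "segment": {"enum": list(SEGMENTS)},
                    "mesh": {"type": "string", "doc": "OBJ/PLY/STL path"},
                    "vertices": {"type": "array", "doc": "inline (n,3) points"},
                },
            },
        },
        "femoral_head": {
            "type": "object",
            "doc": "one of: points (n,3), {bone, vertex_indices}, sphere",
        },
        "muscles": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["name", "origin", "insertion", "biarticular"],
                "doc": "attachment = {bone, vertex_indices (0-based)} or "
                "{bone, centroid}",
            },
        },
    },
}


def _fail(field: str, reason: str):
    raise SchemaError(f"model descriptor: {field}: {reason}")


def _load_mesh(path: Path):
    """Load a surface mesh preserving vertex order and indices.

    ``process=False``/``maintain_order=True`` matter: attachment patches
    reference 0-based vertex indices of the file as written.
    """
    if not path.exists():
        _fail("bones.mesh", f"mesh file not found: {path}")
    m = trimesh.load(path, process=False, maintain_order=True, force="mesh")
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=int)


def _read_bones(doc: dict, base: Path) -> Dict[str, Bone]:
    bones: Dict[str, Bone] = {}
    for i, b in enumerate(doc.get("bones", [])):
        for req in ("name", "segment"):
            if req not in b:
                _fail(f"bones[{i}]", f"missing required field {req!r}")
        name = b["name"]
        if name in bones:
            _fail(f"bones[{i}].name", f"duplicate bone name {name!r}")
        if b["segment"] not in SEGMENTS:
            _fail(f"bones[{i}].segment",
                  f"{b['segment']!r} is not one of {SEGMENTS}")
        if "mesh" in b:
            verts, faces = _load_mesh(base / b["mesh"])
        elif "vertices" in b:
            verts = np.asarray(b["vertices"], dtype=float)
            faces = None
        else:
            _fail(f"bones[{i}] ({name})", "needs either 'mesh' or 'vertices'")
        bones[name] = Bone(name=name, vertices=verts, segment=b["segment"],
                           faces=faces)
    if not bones:
        _fail("bones", "at least one bone is required")
    return bones


def _resolve_site(att: dict, bones: Dict[str, Bone], where: str) -> AttachmentSite:
    if "bone" not in att:
        _fail(where, "missing 'bone'")
    bone = bones.get(att["bone"])
    if bone is None:
        _fail(where, f"unknown bone {att['bone']!r}")
    if "vertex_indices" in att:
        idx = np.asarray(att["vertex_indices"], dtype=int)
        if idx.size == 0:
            _fail(where, "empty vertex_indices patch")
        if idx.min() < 0 or idx.max() >= len(bone.vertices):
            _fail(where,
                  f"vertex index out of range for bone {bone.name!r} "
                  f"({len(bone.vertices)} vertices, 0-based)")
        patch = bone.vertices[idx]
    elif "centroid" in att:
        patch = np.asarray(att["centroid"], dtype=float).reshape(1, 3)
    else:
        _fail(where, "needs either 'vertex_indices' or 'centroid'")
    return AttachmentSite(bone=bone, patch=patch)


def _read_head_points(doc: dict, bones: Dict[str, Bone]):
    head = doc.get("femoral_head")
    if not isinstance(head, dict):
        _fail("femoral_head", "missing or not an object")
    if "sphere" in head:
        s = head["sphere"]
        return None, Sphere(center=np.asarray(s["center"], float),
                            radius=float(s["radius"]))
    if "points" in head:
        return np.asarray(head["points"], dtype=float), None
    if "vertex_indices" in head:
        bone = bones.get(head.get("bone", "femur"))
        if bone is None:
            _fail("femoral_head.bone", f"unknown bone {head.get('bone')!r}")
        idx = np.asarray(head["vertex_indices"], dtype=int)
        return bone.vertices[idx], None
    _fail("femoral_head", "needs 'points', 'vertex_indices', or 'sphere'")


def read_model(descriptor_path, log=None) -> MusculoskeletalModel:
    """Load and validate a model descriptor; derive centroids, the
    sphere-fitted hip center and resting lengths.

    Raises :class:`SchemaError` with the offending field named for any
    malformed descriptor.
    """
    path = Path(descriptor_path)
    if not path.exists():
        raise FileNotFoundError(f"model descriptor not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"model descriptor: invalid JSON ({e})") from e
    if not isinstance(doc, dict):
        _fail("(root)", "descriptor must be a JSON object")
    for req in ("name", "body_mass_g", "bones", "femoral_head", "muscles"):
        if req not in doc:
            _fail("(root)", f"missing required field {req!r}")
    if not (isinstance(doc["body_mass_g"], (int, float)) and doc["body_mass_g"] > 0):
        _fail("body_mass_g", "must be a positive number")

    bones = _read_bones(doc, path.parent)

    muscles: List[Muscle] = []
    for j, mj in enumerate(doc["muscles"]):
        where = f"muscles[{j}]"
        for req in ("name", "origin", "insertion"):
            if req not in mj:
                _fail(where, f"missing required field {req!r}")
        where = f"muscles[{j}] ({mj['name']})"
        origin = _resolve_site(mj["origin"], bones, where + ".origin")
        insertion = _resolve_site(mj["insertion"], bones, where + ".insertion")
        try:
            muscles.append(
                Muscle(
                    name=mj["name"],
                    origin=origin,
                    insertion=insertion,
                    biarticular=bool(
                        mj.get(
                            "biarticular",
                            insertion.bone.segment == "shank-fixed",
                        )
                    ),
                )
            )
        except ValueError as e:
            _fail(where, str(e))
    if not muscles:
        _fail("muscles", "at least one muscle is required")

    head_points, sphere = _read_head_points(doc, bones)
    fe_axis = np.asarray(doc.get("fe_axis", [1.0, 0.0, 0.0]), dtype=float)
    ref_axis = np.asarray(
        doc.get("reference_femur_axis", [0.0, 0.0, 1.0]), dtype=float
    )
    if sphere is None:
        sphere = fit_sphere(head_points)
    hip = HipJointModel(
        center=sphere.center,
        fe_axis=fe_axis,
        zero_pose_femur_axis=ref_axis,
        sphere=sphere,
    )
    if log is not None:
        log.info(
            "model %s: fitted hip sphere center=%s radius=%.4f mm",
            doc["name"], np.round(sphere.center, 4).tolist(), sphere.radius,
        )
    return MusculoskeletalModel(
        name=doc["name"],
        bones=bones,
        muscles=muscles,
        hip=hip,
        body_mass=float(doc["body_mass_g"]),
        pelvis_length=float(doc.get("pelvis_length_mm", 0.0)),
        femur_length=float(doc.get("femur_length_mm", 0.0)),
    )


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serialisable run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_lines(meta: Optional[dict]) -> List[str]:
    lines = [f"# hipmma {__version__}"]
    for key, val in sorted((meta or {}).items()):
        lines.append(f"# {key}: {val}")
    return lines


def write_table(frame: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a DataFrame as CSV with a ``#`` provenance header, full float
    precision (round-trip exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.17g", lineterminator="\n")
    text = "\n".join(_provenance_lines(meta)) + "\n" + buf.getvalue()
    path.write_text(text)


def write_curves(table: CurveTable, path, meta: Optional[dict] = None) -> None:
    """Serialise a :class:`CurveTable` losslessly (provenance header +
    sweep spec + full-precision CSV)."""
    meta = dict(meta or {})
    meta["sweep"] = "%g:%g:%g" % table.sweep_spec
    write_table(table.frame, path, meta)


def read_curves(path) -> CurveTable:
    """Read back a curve CSV written by :func:`write_curves`."""
    path = Path(path)
    sweep_spec = None
    with path.open() as fh:
        header = []
        for line in fh:
            if line.startswith("#"):
                header.append(line)
                if line.startswith("# sweep:"):
                    sweep_spec = tuple(
                        float(x) for x in line.split(":", 1)[1].strip().split(":")
                    )
            else:
                break
    frame = pd.read_csv(path, comment="#")
    if frame.empty:
        frame = pd.DataFrame(columns=CURVE_COLUMNS)
    # integral-looking floats (e.g. whole-degree angles) come back as ints
    for col in frame.columns:
        if col not in ("model", "muscle", "strain_class"):
            frame[col] = frame[col].astype(float)
    if sweep_spec is None:
        angles = sorted(frame["angle_deg"].unique()) if len(frame) else [0.0, 1.0]
        step = angles[1] - angles[0] if len(angles) > 1 else 1.0
        sweep_spec = (angles[0], angles[-1], step)
    return CurveTable(frame, sweep_spec)
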