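# Model descriptor schema

A model is described by a JSON object (conventionally `model.json`) living
next to the mesh files it references. `hipmma.io.read_model` validates the
document and raises `SchemaError` naming the offending field; the same
structure is available machine-readably as `hipmma.io.DESCRIPTOR_SCHEMA`.

```json
{
  "name": "specimen_or_model_id",
  "body_mass_g": 450.0,
  "pelvis_length_mm": 30.0,
  "femur_length_mm": 35.0,
  "fe_axis": [1.0, 0.0, 0.0],
  "reference_femur_axis": [0.0, 0.0, 1.0],
  "bones": [
    {"name": "pelvis", "segment": "pelvis-fixed", "mesh": "pelvis.obj"},
    {"name": "femur",  "segment": "femur-fixed",  "mesh": "femur.obj"},
    {"name": "tibia",  "segment": "shank-fixed",  "mesh": "tibia.obj"},
    {"name": "fibula", "segment": "shank-fixed",  "mesh": "fibula.obj"}
  ],
  "femoral_head": {"points": [[0.1, -0.2, 3.4], "..."]},
  "muscles": [
    {
      "name": "gluteus_medius",
      "biarticular": false,
      "origin":    {"bone": "pelvis", "vertex_indices": [1282, 1283, 1284]},
      "insertion": {"bone": "femur",  "centroid": [3.5, -0.64, -2.1]}
    }
  ]
}
```

## Fields

* **name** — free-text identifier; copied into every output row.
* **body_mass_g** — positive; used for the mass^0.33 normalization. Any
  mass unit works as long as every compared model uses the same one.
* **pelvis_length_mm / femur_length_mm** — effective bone lengths for the
  relative-length summary and the origin-shift analysis. Optional: when
  absent, the maximum pairwise vertex distance of the corresponding bone
  mesh is used (a caliper length; supply explicit values when that is not
  what you mean).
* **fe_axis** — the flexion–extension hinge axis (normal of the
  parasagittal plane), normalised by the reader. Default `[1, 0, 0]`,
  which assumes the standardised orientation: x medio-lateral, y cranial,
  z ventral.
* **reference_femur_axis** — femur long-axis direction at the 90°/90°
  reference pose; metadata for importers, default `[0, 0, 1]`.
* **bones** — each entry needs `name`, `segment` (one of `pelvis-fixed`,
  `femur-fixed`, `shank-fixed`: the rigid body it follows during the hip
  sweep), and either `mesh` (OBJ/PLY/STL path relative to the descriptor)
  or inline `vertices` (list of `[x, y, z]` in mm). Meshes are read with
  vertex order preserved exactly as on disk.
* **femoral_head** — one of:
  * `{"points": [[x, y, z], ...]}` — explicit head surface samples
    (≥ 4, non-coplanar) to sphere-fit;
  * `{"bone": "femur", "vertex_indices": [...]}` — sample the named bone's
    vertices;
  * `{"sphere": {"center": [x, y, z], "radius": r}}` — skip fitting.
* **muscles** — each entry needs `name`, `origin`, `insertion`, and
  `biarticular` (must agree with the insertion bone's segment: `true` iff
  shank-fixed). An attachment is `{"bone": ..., "vertex_indices": [...]}`
  (a patch whose unweighted vertex mean is the working centroid) or
  `{"bone": ..., "centroid": [x, y, z]}` (an explicitly placed point,
  equivalent to a single-vertex patch). Origins must lie on a
  pelvis-fixed bone.

**Vertex indices are 0-based.** OBJ files are 1-based on disk; the reader
performs the conversion, so index 0 addresses the first `v` line of the
file.
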