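"""Shared fixtures: synthetic models generated once per session."""

import numpy as np
import pytest

from hipmma import io, synthetic
from hipmma.geometry import Sphere
from hipmma.model import (
    AttachmentSite,
    Bone,
    HipJointModel,
    Muscle,
    MusculoskeletalModel,
)


@pytest.fixture(scope="session")
def model_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("models")


@pytest.fixture(scope="session")
def default_model(model_dir):
    """The canonical generic synthetic model, loaded via the standard I/O
    path, together with its ground truth."""
    spec = synthetic.SyntheticModelSpec()
    path, truth = synthetic.generate_model(spec, model_dir / "default")
    return io.read_model(path), truth


@pytest.fixture(scope="session")
def cohort(model_dir):
    """Four-model comparative cohort (distinct morphotypes and masses)."""
    out = []
    for spec in synthetic.cohort_specs(4):
        path, truth = synthetic.generate_model(spec, model_dir / spec.name)
        out.append((io.read_model(path), truth, spec))
    return out


def toy_model(
    origin=(0.0, 5.0, 0.0),
    insertion=(3.0, -4.0, 0.0),
    hip_center=(0.0, 0.0, 0.0),
    fe_axis=(1.0, 0.0, 0.0),
    body_mass=1.0,
    insertion_segment="femur-fixed",
) -> MusculoskeletalModel:
    """Minimal single-muscle model with explicitly placed centroids, for
    closed-form geometry checks."""
    pelvis = Bone("pelvis", np.atleast_2d(np.asarray(origin, float)), "pelvis-fixed")
    femur = Bone("femur", np.atleast_2d(np.asarray(insertion, float)), insertion_segment)
    muscle = Muscle(
        name="toy_extensor",
        origin=AttachmentSite(pelvis, np.atleast_2d(np.asarray(origin, float))),
        insertion=AttachmentSite(femur, np.atleast_2d(np.asarray(insertion, float))),
        biarticular=insertion_segment == "shank-fixed",
    )
    hip = HipJointModel(
        center=np.asarray(hip_center, float),
        fe_axis=np.asarray(fe_axis, float),
        sphere=Sphere(np.asarray(hip_center, float), 1.0),
    )
    return MusculoskeletalModel(
        name="toy",
        bones={"pelvis": pelvis, "femur": femur},
        muscles=[muscle],
        hip=hip,
        body_mass=body_mass,
        pelvis_length=10.0,
        femur_length=10.0,
    )
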