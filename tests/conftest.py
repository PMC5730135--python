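import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dispquant as dq
from dispquant.registration import LabelMap

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=20,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> dq.PhantomSpec:
    return dq.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def phantom_t1(default_spec):
    """T1 intensity volume and label map of the default phantom."""
    return dq.make_phantom(default_spec)


def make_box_labelmap(lo, hi, value=1, name="maxilla_upper_teeth",
                      shape=(140, 100, 140), spacing=0.5):
    """Rasterise a single axis-aligned box as a label map."""
    org = spacing / 2
    axes = [org + np.arange(shape[d]) * spacing for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    mask = ((X >= lo[0]) & (X <= hi[0]) & (Y >= lo[1]) & (Y <= hi[1])
            & (Z >= lo[2]) & (Z <= hi[2]))
    return LabelMap((value * mask).astype(np.uint8), (spacing,) * 3,
                    (org,) * 3, label_names={value: name})


@pytest.fixture(scope="session")
def box_jaw_mesh():
    """A 40 x 40 mm flat-anterior-face jaw box (20 mm deep), as a mesh."""
    labels = make_box_labelmap((12, 10, 12), (52, 30, 52))
    return dq.extract_surface(labels, 1)


@pytest.fixture(scope="session")
def advanced_box_jaw(box_jaw_mesh):
    """The same jaw advanced 5 mm along its anterior (+y) face normal."""
    return box_jaw_mesh.transformed(dq.RigidTransform.from_translation((0, 5, 0)))


@pytest.fixture(scope="session")
def sphere_labelmap():
    """Digital sphere of radius 20 mm at 0.5 mm spacing."""
    shape, spacing = (96, 96, 96), 0.5
    org = spacing / 2
    axes = [org + np.arange(n) * spacing - 24.0 for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    mask = (X**2 + Y**2 + Z**2) <= 20.0**2
    return LabelMap(mask.astype(np.uint8), (spacing,) * 3, (org - 24.0,) * 3,
                    label_names={1: "soft_tissue"})


@pytest.fixture(scope="session")
def sphere_mesh(sphere_labelmap):
    return dq.extract_surface(sphere_labelmap, 1)


@pytest.fixture(scope="session")
def surgical_subject(default_spec, phantom_t1):
    """One phantom subject with a known plan: maxilla +5 mm, mandible +9 mm,
    soft coupling 1.0, no jitter, no nuisance pose."""
    vol1, lab1 = phantom_t1
    plan = dq.SurgicalPlan(maxilla_advance_mm=5.0, mandible_advance_mm=9.0,
                           soft_coupling_maxilla=1.0,
                           soft_coupling_mandible=1.0)
    vol2, lab2, truth = dq.apply_surgery(vol1, lab1, plan, spec=default_spec,
                                         seed=7)
    return dq.PhantomSubject("known_plan", default_spec, plan, vol1, lab1,
                             vol2, lab2, truth)


@pytest.fixture(scope="session")
def posed_subject(default_spec, phantom_t1):
    """Subject with surgery plus a 2-degree / 2-mm nuisance head pose."""
    vol1, lab1 = phantom_t1
    pose = dq.RigidTransform(rotation_deg=(2, -2, 2), translation_mm=(2, -2, 2),
                             center_mm=(44, 52, 52))
    plan = dq.SurgicalPlan(maxilla_advance_mm=4.0, mandible_advance_mm=8.0,
                           head_pose=pose, soft_noise_sd_mm=0.5)
    vol2, lab2, truth = dq.apply_surgery(vol1, lab1, plan, spec=default_spec,
                                         seed=9)
    return dq.PhantomSubject("posed", default_spec, plan, vol1, lab1,
                             vol2, lab2, truth)


@pytest.fixture(scope="session")
def cohort_report():
    """Full-pipeline 8-subject cohort at study conditions: soft coupling 0.9,
    low soft-tissue jitter, duplicated measurement sessions."""
    cfg = dq.PipelineConfig(n_subjects=8, seed=11)
    cfg.plan_distribution = dq.PlanDistribution(soft_coupling=(0.9, 0.9),
                                                soft_noise_sd_mm=0.1)
    return dq.run_cohort(cfg)
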