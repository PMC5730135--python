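"""End-to-end study pipeline: simulate/ingest -> register -> extract ->
measure -> correlate, per subject and per cohort.

Per subject the pipeline recovers the cranial-base superimposition, maps the
follow-up (T2) meshes into the reference (T1) frame, paints the measurement
areas on the T1 meshes and summarises the signed closest-point displacement
of each area.  Per cohort it assembles the subjects x areas measurement
table, re-measures it for the repeatability analysis, and renders the four
report tables: repeatability (ICC + paired differences), descriptives, and
the maxillary and mandibular Spearman correlation matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import displacement as disp
from . import stats as st
from .phantom import (PhantomSpec, PhantomSubject, PlanDistribution,
                      make_cohort)
from .registration import (RegistrationConfig, RegistrationResult,
                           register_rigid, resample)
from .surface import SurfaceMesh, extract_surface, write_stl

log = logging.getLogger("dispquant")

MEASURED_LABELS = ("maxilla_upper_teeth", "mandible_lower_teeth", "soft_tissue")


@dataclass(frozen=True)
class RegionSpec:
    """Declarative area definition: seed point + radius on one label's mesh."""

    name: str
    label: str
    seed_point: tuple[float, float, float]
    radius_mm: float
    metric: str = "euclidean"


#: default placement of the 15 study areas on the default phantom, chosen so
#: each patch sits far enough from box edges and soft-tissue zone boundaries
#: that a sagittal advancement reads as a clean straight-ahead displacement.
STUDY_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec("A Point", "maxilla_upper_teeth", (44, 46, 68), 2.5),
    RegionSpec("Upper Incisors", "maxilla_upper_teeth", (44, 46, 60), 2.5),
    RegionSpec("Pogonion", "mandible_lower_teeth", (44, 46, 28), 2.5),
    RegionSpec("Lower Incisors", "mandible_lower_teeth", (44, 46, 34), 2.5),
    RegionSpec("Nasal Tip", "soft_tissue", (44, 78, 80), 2.5),
    RegionSpec("Soft A Point", "soft_tissue", (44, 78, 66), 2.5),
    RegionSpec("Upper Lip", "soft_tissue", (44, 78, 60), 2.5),
    RegionSpec("Left Cheilion", "soft_tissue", (34, 78, 60), 2.0),
    RegionSpec("Right Cheilion", "soft_tissue", (54, 78, 60), 2.0),
    RegionSpec("Left Supra Cheilion", "soft_tissue", (36, 78, 65), 2.5),
    RegionSpec("Right Supra Cheilion", "soft_tissue", (52, 78, 65), 2.5),
    RegionSpec("Left Sub Cheilion", "soft_tissue", (34, 78, 30), 2.5),
    RegionSpec("Right Sub Cheilion", "soft_tissue", (54, 78, 30), 2.5),
    RegionSpec("Lower Lip", "soft_tissue", (44, 78, 30), 2.5),
    RegionSpec("Soft Pogonion", "soft_tissue", (44, 78, 24), 2.5),
)


@dataclass
class PipelineConfig:
    """Single flat configuration for a run; hashed into every output."""

    mode: str = "phantom"                    # phantom | volumes | meshes
    n_subjects: int = 8
    seed: int = 42
    target_spacing_mm: float = 0.5
    direction: str = "t1-to-t2"              # or "t2-to-t1"
    alpha: float = 0.05
    regions: tuple[RegionSpec, ...] = STUDY_REGIONS
    regions_file: str | None = None
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    plan_distribution: PlanDistribution = field(default_factory=PlanDistribution)
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    repeat_seed_jitter_mm: float = 0.0       # second-session re-paint jitter
    smooth_sigma_voxels: float = 0.8
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps({
            "mode": self.mode, "n": self.n_subjects, "seed": self.seed,
            "spacing": self.target_spacing_mm, "direction": self.direction,
            "alpha": self.alpha,
            "regions": [(r.name, r.label, r.seed_point, r.radius_mm, r.metric)
                        for r in self.regions],
            "jitter": self.repeat_seed_jitter_mm,
            "sigma": self.smooth_sigma_voxels}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        for key in ("mode", "n_subjects", "seed", "target_spacing_mm",
                    "direction", "alpha", "regions_file", "out_dir",
                    "repeat_seed_jitter_mm", "smooth_sigma_voxels"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if cfg.regions_file:
            p = Path(cfg.regions_file)
            if not p.exists():
                raise StageError("configure",
                                 f"region definition file not found: {p}")
            cfg.regions = tuple(
                RegionSpec(d["name"], d["label"], tuple(d["seed_point"]),
                           float(d["radius_mm"]), d.get("metric", "euclidean"))
                for d in json.loads(p.read_text()))
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name travels with the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage


@dataclass
class SubjectReport:
    subject_id: str
    registration: RegistrationResult
    summaries: pd.DataFrame                  # Region, N, Min, Max, Mean, ...
    meshes_t1: dict[str, SurfaceMesh]
    meshes_t2_aligned: dict[str, SurfaceMesh]
    provenance: dict


@dataclass
class CohortReport:
    session1: pd.DataFrame                   # subjects x areas mean displacement
    session2: pd.DataFrame
    descriptives: pd.DataFrame               # Table-2 analogue
    repeatability: pd.DataFrame              # Table-1 analogue (ICC + diffs)
    corr_maxillary: st.CorrelationMatrix     # Table-3 analogue
    corr_mandibular: st.CorrelationMatrix    # Table-4 analogue
    subject_reports: list[SubjectReport]
    failures: dict[str, str]
    config_hash: str


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        log.info("stage %-10s %6.2f s", name, time.perf_counter() - t0)
        return result
    return wrap


def _measure(meshes_src: dict[str, SurfaceMesh],
             meshes_dst: dict[str, SurfaceMesh],
             regions: tuple[RegionSpec, ...],
             seed_jitter: np.ndarray | None = None) -> pd.DataFrame:
    prox = {label: disp.TriangleProximity(mesh)
            for label, mesh in meshes_dst.items()}
    rows = []
    for i, spec in enumerate(regions):
        if spec.label not in meshes_src:
            raise StageError("measure", f"no mesh for label {spec.label!r}")
        seed = np.asarray(spec.seed_point, dtype=float)
        if seed_jitter is not None:
            seed = seed + seed_jitter[i]
        region = disp.paint_region(meshes_src[spec.label], seed,
                                   spec.radius_mm, metric=spec.metric,
                                   name=spec.name)
        summary = disp.region_summary(region, meshes_src[spec.label],
                                      proximity=prox[spec.label],
                                      warn_sign_mixing=False)
        rows.append(summary.to_dict())
    return pd.DataFrame(rows)


def run_subject(config: PipelineConfig, subject: PhantomSubject,
                seed_jitter: np.ndarray | None = None) -> SubjectReport:
    """Run the full per-subject protocol and return its report.

    Stages: resample (if needed) -> cranial-base registration -> surface
    extraction -> region measurement.  A failure aborts the subject with a
    stage-named error.
    """
    if config.regions_file and not Path(config.regions_file).exists():
        raise StageError("configure",
                         f"region definition file not found: "
                         f"{config.regions_file}")

    def _resample_stage():
        vols = {}
        for tp, vol, lab in (("t1", subject.volume_t1, subject.labels_t1),
                             ("t2", subject.volume_t2, subject.labels_t2)):
            vols[tp] = (resample(vol, config.target_spacing_mm, "trilinear"),
                        resample(lab, config.target_spacing_mm, "nearest"))
        return vols

    vols = _stage("resample")(_resample_stage)

    (vol1, lab1), (vol2, lab2) = vols["t1"], vols["t2"]
    reg = _stage("register")(register_rigid, vol1, vol2, lab1,
                             config.registration, mask_label="cranial_base")

    def _extract_stage():
        t1, t2 = {}, {}
        for label in MEASURED_LABELS:
            t1[label] = extract_surface(lab1, label, config.smooth_sigma_voxels)
            mesh2 = extract_surface(lab2, label, config.smooth_sigma_voxels)
            t2[label] = mesh2.transformed(reg.transform)
        return t1, t2

    meshes_t1, meshes_t2 = _stage("extract")(_extract_stage)

    if config.direction == "t2-to-t1":
        src, dst = meshes_t2, meshes_t1
    else:
        src, dst = meshes_t1, meshes_t2
    summaries = _stage("measure")(_measure, src, dst, config.regions,
                                  seed_jitter)

    provenance = {"subject": subject.subject_id,
                  "config_hash": config.config_hash(),
                  "direction": config.direction,
                  "registration": reg.settings,
                  "registration_converged": reg.converged,
                  "final_mi_bits": reg.final_mi_bits,
                  "mesh_checksums": {k: m.checksum()
                                     for k, m in meshes_t1.items()}}
    report = SubjectReport(subject.subject_id, reg, summaries, meshes_t1,
                           meshes_t2, provenance)
    if config.out_dir:
        _write_subject_outputs(config, report)
    return report


def _write_subject_outputs(config: PipelineConfig, report: SubjectReport):
    out = Path(config.out_dir) / report.subject_id
    out.mkdir(parents=True, exist_ok=True)
    report.registration.transform.save(out / "t2_to_t1_transform.json")
    for label, mesh in report.meshes_t1.items():
        write_stl(mesh, out / f"{label}_t1.stl")
    for label, mesh in report.meshes_t2_aligned.items():
        write_stl(mesh, out / f"{label}_t2_aligned.stl")
    report.summaries.to_csv(out / "displacement_summary.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(report.provenance,
                                                    indent=2, default=str))


def run_cohort(config: PipelineConfig,
               subjects: list[PhantomSubject] | None = None) -> CohortReport:
    """Run every subject and assemble the four study-report tables."""
    if config.mode != "phantom" and subjects is None:
        raise StageError("configure",
                         f"mode {config.mode!r} requires preloaded subjects")
    if subjects is None:
        subjects = make_cohort(config.n_subjects, config.phantom_spec,
                               config.plan_distribution, seed=config.seed)
    if len(subjects) < 3:
        raise StageError("correlate",
                         "correlation analysis needs at least 3 subjects")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    reports, failures = [], {}
    rows1, rows2 = {}, {}
    for subject in subjects:
        jitter = None
        if config.repeat_seed_jitter_mm > 0:
            jitter = rng.normal(0.0, config.repeat_seed_jitter_mm,
                                (len(config.regions), 3))
        try:
            report = run_subject(config, subject)
            if jitter is None:
                second = report.summaries
            else:
                src = report.meshes_t1 if config.direction != "t2-to-t1" \
                    else report.meshes_t2_aligned
                dst = report.meshes_t2_aligned \
                    if config.direction != "t2-to-t1" else report.meshes_t1
                second = _measure(src, dst, config.regions, jitter)
        except StageError as exc:
            failures[subject.subject_id] = str(exc)
            log.warning("subject %s failed: %s", subject.subject_id, exc)
            continue
        reports.append(report)
        rows1[subject.subject_id] = dict(
            zip(report.summaries["Region"], report.summaries["Mean"]))
        rows2[subject.subject_id] = dict(zip(second["Region"], second["Mean"]))

    if len(rows1) < 3:
        raise StageError("correlate",
                         f"only {len(rows1)} subjects succeeded; "
                         "correlation needs at least 3")
    session1 = pd.DataFrame.from_dict(rows1, orient="index")
    session2 = pd.DataFrame.from_dict(rows2, orient="index")

    desc = st.descriptives(session1)
    diffs = st.difference_report(session1, session2)
    icc_rows = {}
    for area in session1.columns:
        res = st.icc_repeatability(session1[area], session2[area])
        icc_rows[area] = {"ICC": res.icc, "ICC_CI_low": res.ci95[0],
                          "ICC_CI_high": res.ci95[1], "model": res.model_tag}
    repeat = pd.concat([pd.DataFrame.from_dict(icc_rows, orient="index"),
                        diffs], axis=1)
    cm_max = st.correlation_matrix(session1, "maxillary", alpha=config.alpha)
    cm_man = st.correlation_matrix(session1, "mandibular", alpha=config.alpha)

    report = CohortReport(session1, session2, desc, repeat, cm_max, cm_man,
                          reports, failures, config.config_hash())
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        session1.to_csv(out / "measurements_session1.csv")
        session2.to_csv(out / "measurements_session2.csv")
        desc.to_csv(out / "descriptives.csv")
        repeat.to_csv(out / "repeatability.csv")
        cm_max.to_frame().to_csv(out / "correlation_maxillary.csv")
        cm_man.to_frame().to_csv(out / "correlation_mandibular.csv")
        (out / "correlation_maxillary.txt").write_text(cm_max.render() + "\n")
        (out / "correlation_mandibular.txt").write_text(cm_man.render() + "\n")
        (out / "run.json").write_text(json.dumps(
            {"config_hash": report.config_hash, "failures": failures,
             "n_subjects": len(reports)}, indent=2))
    return report
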