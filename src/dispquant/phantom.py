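"""Synthetic two-time-point phantoms with known per-label rigid transforms.

The phantom stands in for a bimaxillary-advancement patient imaged before
surgery (T1) and at follow-up (T2).  Anatomy is deliberately primitive —
axis-aligned boxes for the cranial base, maxilla (+ upper teeth) and
mandible (+ lower teeth), and a facial soft-tissue slab — because the
measurement method only needs labelled surfaces and ground-truth motion:
flat anterior jaw faces make translation along the face normal an
analytically exact displacement.

Surgery is a sagittal (+y, anterior) translation per jaw.  The soft-tissue
shell is split into three coupling zones by height: a mandibular and a
maxillary zone that each move as a scaled copy (``coupling ratio`` ×) of the
underlying jaw's advancement plus per-subject isotropic jitter, and a nasal
zone that does not follow the jaws at all (it only jitters) — emulating the
clinical observation that nasal-tip change does not track maxillary
advancement.  A rigid whole-head nuisance pose is applied to everything at
T2, so the registration stage has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .registration import LabelMap, RigidTransform, Volume

LABEL_NAMES = {1: "maxilla_upper_teeth", 2: "mandible_lower_teeth",
               3: "soft_tissue", 4: "cranial_base"}
MAXILLA, MANDIBLE, SOFT, CRANIAL_BASE = 1, 2, 3, 4

#: soft-tissue coupling zones, keyed by ground-truth name
SOFT_ZONES = ("soft_mandibular", "soft_maxillary", "soft_nasal")


@dataclass(frozen=True)
class Box:
    """Axis-aligned box primitive, world-mm corners ``lo``/``hi``."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        if not all(h > l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box: lo={self.lo} hi={self.hi}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return np.all((pts >= lo) & (pts <= hi), axis=-1)

    def volume_mm3(self) -> float:
        return float(np.prod(np.asarray(self.hi) - np.asarray(self.lo)))

    def intersects(self, other: "Box") -> bool:
        return all(l1 < h2 and l2 < h1 for l1, h1, l2, h2 in
                   zip(self.lo, self.hi, other.lo, other.hi))


def _default_geometry() -> dict[str, Box]:
    # x: lateral (88 mm extent), y: posterior->anterior (104 mm), z: inf->sup
    # (104 mm).  A closest-point query from an anterior-face vertex reads the
    # pure advancement only while every *other* surface of the same label
    # (posterior face, side faces, the tear between soft-tissue coupling
    # zones) stays farther away than the displacement itself, so the pieces
    # are deliberately deep (jaws 32 mm, shell 30 mm) and the measured faces
    # wide enough to give the painted areas >= 15 mm of in-plane margin.
    return {
        "mandible": Box((24, 14, 8), (64, 46, 48)),
        "maxilla": Box((24, 14, 52), (64, 46, 76)),
        "cranial_base": Box((24, 12, 78), (64, 46, 88)),
        "soft_shell": Box((14, 48, 10), (74, 78, 84)),
    }


@dataclass
class PhantomSpec:
    """Geometry, grid and imaging parameters of one synthetic subject.

    The default grid is 176 x 208 x 208 voxels at 0.5 mm isotropic spacing
    (the working resolution the scans are reformatted to), with voxel 0
    centred at 0.25 mm so that integer-mm box faces fall exactly between
    voxel centres.  Intensities: bone 1200, soft tissue 300, air 0, with
    additive Gaussian acquisition noise (sd 30 by default) — arbitrary but
    fixed values; only their ordering matters to the MI registration.
    """

    grid_shape: tuple[int, int, int] = (176, 208, 208)
    spacing_mm: float = 0.5
    geometry: dict[str, Box] = field(default_factory=_default_geometry)
    #: z thresholds splitting the shell into mandibular / maxillary / nasal zones
    soft_zone_splits_mm: tuple[float, float] = (50.0, 76.0)
    noise_sd: float = 30.0
    intensities: dict[str, float] = field(
        default_factory=lambda: {"bone": 1200.0, "soft": 300.0, "air": 0.0})
    #: air-filled cavities inside the cranial base ("sinuses"): without
    #: internal structure a uniform slab leaves in-plane translations almost
    #: unconstrained by mutual information
    n_base_cavities: int = 14
    base_cavity_radius_mm: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    @property
    def origin(self) -> tuple[float, float, float]:
        return (self.spacing_mm / 2,) * 3

    def validate(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        required = {"mandible", "maxilla", "cranial_base", "soft_shell"}
        missing = required - set(self.geometry)
        if missing:
            raise ValueError(f"missing primitives: {sorted(missing)}")
        extent = np.asarray(self.grid_shape) * self.spacing_mm
        for name, box in self.geometry.items():
            if np.any(np.asarray(box.lo) <= 0) or np.any(np.asarray(box.hi) >= extent):
                raise ValueError(
                    f"primitive {name!r} does not fit strictly inside the "
                    f"grid (extent {tuple(extent)} mm): lo={box.lo} hi={box.hi}")
        names = sorted(self.geometry)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.geometry[a].intersects(self.geometry[b]):
                    raise ValueError(f"primitives {a!r} and {b!r} overlap")


@dataclass
class SurgicalPlan:
    """Per-jaw sagittal advancement plus nuisance head pose and soft coupling."""

    maxilla_advance_mm: float = 0.0
    mandible_advance_mm: float = 0.0
    head_pose: RigidTransform = field(default_factory=RigidTransform)
    soft_coupling_maxilla: float = 0.9
    soft_coupling_mandible: float = 0.9
    soft_noise_sd_mm: float = 0.0

    def validate(self) -> None:
        if self.maxilla_advance_mm < 0 or self.mandible_advance_mm < 0:
            raise ValueError("advancements must be non-negative")
        for r in (self.soft_coupling_maxilla, self.soft_coupling_mandible):
            if not 0.0 <= r <= 1.5:
                raise ValueError(f"coupling ratio {r} outside [0, 1.5]")
        if self.soft_noise_sd_mm < 0:
            raise ValueError("soft-tissue jitter sd must be non-negative")

    def is_null(self) -> bool:
        return (self.maxilla_advance_mm == 0 and self.mandible_advance_mm == 0
                and self.soft_noise_sd_mm == 0 and self.head_pose.is_identity())


# --------------------------------------------------------------------------
# T1 synthesis
# --------------------------------------------------------------------------

def base_cavities(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-subject cavity centres/radii inside the base slab."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCA]))
    box = spec.geometry["cranial_base"]
    lo = np.asarray(box.lo) + 3.0
    hi = np.asarray(box.hi) - 3.0
    centers = rng.uniform(lo, hi, (spec.n_base_cavities, 3))
    radii = rng.uniform(*spec.base_cavity_radius_mm, spec.n_base_cavities)
    return centers, radii


def _clean_intensity(labels: LabelMap, spec: PhantomSpec) -> np.ndarray:
    """Noiseless T1-frame intensity: label LUT plus cranial-base cavities."""
    inten = spec.intensities
    lut = np.array([inten["air"], inten["bone"], inten["bone"],
                    inten["soft"], inten["bone"]], dtype=np.float32)
    data = lut[labels.data]
    if spec.n_base_cavities > 0:
        centers, radii = base_cavities(spec)
        base = labels.data == CRANIAL_BASE
        nz = np.nonzero(base)
        pts = (np.stack(nz, axis=-1) * np.asarray(labels.spacing)
               + np.asarray(labels.origin))
        inside = np.zeros(len(pts), dtype=bool)
        for c, r in zip(centers, radii):
            inside |= np.einsum("ij,ij->i", pts - c, pts - c) <= r * r
        data[nz[0][inside], nz[1][inside], nz[2][inside]] = inten["air"]
    return data


def _render_t1(labels: LabelMap, spec: PhantomSpec,
               rng: np.random.Generator) -> Volume:
    data = _clean_intensity(labels, spec)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, data.shape).astype(np.float32)
    return Volume(data.astype(np.float32), labels.spacing, labels.origin,
                  labels.direction.copy())


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Rasterise the T1 subject: intensity volume plus matching label map."""
    spec.validate()
    sp, org = spec.spacing_mm, np.asarray(spec.origin)
    axes = [org[d] + np.arange(spec.grid_shape[d]) * sp for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)

    def box_mask(box: Box) -> np.ndarray:
        return ((X >= box.lo[0]) & (X <= box.hi[0]) &
                (Y >= box.lo[1]) & (Y <= box.hi[1]) &
                (Z >= box.lo[2]) & (Z <= box.hi[2]))

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[box_mask(spec.geometry["soft_shell"])] = SOFT
    labels[box_mask(spec.geometry["cranial_base"])] = CRANIAL_BASE
    labels[box_mask(spec.geometry["maxilla"])] = MAXILLA
    labels[box_mask(spec.geometry["mandible"])] = MANDIBLE
    if not (labels == CRANIAL_BASE).any():
        raise ValueError("cranial-base label is empty on this grid")
    lmap = LabelMap(labels, (sp,) * 3, tuple(org), label_names=dict(LABEL_NAMES))
    rng = np.random.default_rng(spec.seed)
    return _render_t1(lmap, spec, rng), lmap


# --------------------------------------------------------------------------
# T2 surgery
# --------------------------------------------------------------------------

def _soft_zone_masks(labels: LabelMap, z_world: np.ndarray,
                     splits: tuple[float, float]) -> dict[str, np.ndarray]:
    soft = labels.data == SOFT
    lo, hi = splits
    return {"soft_mandibular": soft & (z_world < lo),
            "soft_maxillary": soft & (z_world >= lo) & (z_world < hi),
            "soft_nasal": soft & (z_world >= hi)}


def apply_surgery(volume_t1: Volume, labels_t1: LabelMap, plan: SurgicalPlan,
                  spec: PhantomSpec | None = None, seed: int = 0,
                  ) -> tuple[Volume, LabelMap, dict[str, RigidTransform]]:
    """Simulate the post-surgical scan and return per-piece ground truth.

    Each rigid piece (cranial base, jaws, three soft-tissue zones) moves by
    its own transform; the whole subject is additionally moved by the
    nuisance head pose.  Ground-truth transforms map T1 geometry to T2
    geometry in world mm.  Any piece pushed outside the grid raises.
    """
    plan.validate()
    spec = spec or PhantomSpec(grid_shape=labels_t1.shape,
                               spacing_mm=labels_t1.spacing[0])
    for name, lab in ((MAXILLA, "maxilla"), (MANDIBLE, "mandible"),
                      (SOFT, "soft tissue")):
        if not (labels_t1.data == name).any():
            raise ValueError(f"label for {lab} is empty")

    if plan.is_null():
        return (volume_t1.copy(), labels_t1.copy(),
                {name: RigidTransform() for name in
                 ("cranial_base", "maxilla_upper_teeth", "mandible_lower_teeth",
                  *SOFT_ZONES)})

    rng = np.random.default_rng(seed)
    jitter = {z: (rng.normal(0.0, plan.soft_noise_sd_mm, 3)
                  if plan.soft_noise_sd_mm > 0 else np.zeros(3))
              for z in SOFT_ZONES}
    adv_max = np.array([0.0, plan.maxilla_advance_mm, 0.0])
    adv_man = np.array([0.0, plan.mandible_advance_mm, 0.0])
    local = {
        "cranial_base": RigidTransform(),
        "maxilla_upper_teeth": RigidTransform.from_translation(adv_max),
        "mandible_lower_teeth": RigidTransform.from_translation(adv_man),
        "soft_maxillary": RigidTransform.from_translation(
            plan.soft_coupling_maxilla * adv_max + jitter["soft_maxillary"]),
        "soft_mandibular": RigidTransform.from_translation(
            plan.soft_coupling_mandible * adv_man + jitter["soft_mandibular"]),
        "soft_nasal": RigidTransform.from_translation(jitter["soft_nasal"]),
    }
    truth = {name: plan.head_pose.compose(t) for name, t in local.items()}

    z_world = (np.asarray(labels_t1.origin)[2]
               + np.arange(labels_t1.shape[2]) * labels_t1.spacing[2]
               )[None, None, :]
    piece_masks = {"cranial_base": labels_t1.data == CRANIAL_BASE,
                   "maxilla_upper_teeth": labels_t1.data == MAXILLA,
                   "mandible_lower_teeth": labels_t1.data == MANDIBLE,
                   **_soft_zone_masks(labels_t1, z_world,
                                      spec.soft_zone_splits_mm)}
    piece_label = {"cranial_base": CRANIAL_BASE, "maxilla_upper_teeth": MAXILLA,
                   "mandible_lower_teeth": MANDIBLE, "soft_mandibular": SOFT,
                   "soft_maxillary": SOFT, "soft_nasal": SOFT}

    lo, hi = labels_t1.world_bounds()
    sp = np.asarray(labels_t1.spacing)
    org = np.asarray(labels_t1.origin)
    shape = np.asarray(labels_t1.shape)
    out = np.zeros(labels_t1.shape, dtype=np.uint8)
    t1_clean = _clean_intensity(labels_t1, spec)
    out_inten = np.full(labels_t1.shape, spec.intensities["air"],
                        dtype=np.float32)
    # later entries override earlier ones where pieces collide after surgery
    order = ["soft_nasal", "soft_maxillary", "soft_mandibular", "cranial_base",
             "maxilla_upper_teeth", "mandible_lower_teeth"]
    for name in order:
        mask = piece_masks[name]
        if not mask.any():
            continue
        t = truth[name]
        # move the piece's bounding-box corners to bound the T2 footprint
        nz = np.nonzero(mask)
        blo = np.array([i.min() for i in nz]) * sp + org
        bhi = np.array([i.max() for i in nz]) * sp + org
        corners = np.array([[x, y, z] for x in (blo[0], bhi[0])
                            for y in (blo[1], bhi[1]) for z in (blo[2], bhi[2])])
        moved = t.apply_points(corners)
        if np.any(moved < lo - sp / 2) or np.any(moved > hi + sp / 2):
            raise ValueError(
                f"piece {name!r} is pushed outside the grid by the plan")
        # inverse mapping over the footprint only: which T1 voxel does each
        # T2 voxel come from?
        ilo = np.maximum(0, np.floor((moved.min(0) - org) / sp).astype(int) - 1)
        ihi = np.minimum(shape, np.ceil((moved.max(0) - org) / sp).astype(int) + 2)
        sub = tuple(slice(l, h) for l, h in zip(ilo, ihi))
        sub_axes = [org[d] + np.arange(ilo[d], ihi[d]) * sp[d] for d in range(3)]
        gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
        sub_centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        src = t.inverse().apply_points(sub_centers)
        idx = np.rint((src - org) / sp).astype(int)
        valid = np.all((idx >= 0) & (idx < shape), axis=1)
        hit = np.zeros(len(sub_centers), dtype=bool)
        iv = idx[valid]
        hit[valid] = mask[iv[:, 0], iv[:, 1], iv[:, 2]]
        region = out[sub]
        flat = region.reshape(-1)
        flat[hit] = piece_label[name]
        out[sub] = flat.reshape(region.shape)
        # carry the piece's (noiseless) T1 intensity, cavities included
        ireg = out_inten[sub]
        iflat = ireg.reshape(-1)
        ih = idx[hit]
        iflat[hit] = t1_clean[ih[:, 0], ih[:, 1], ih[:, 2]]
        out_inten[sub] = iflat.reshape(ireg.shape)

    labels_t2 = LabelMap(out, labels_t1.spacing, labels_t1.origin,
                         labels_t1.direction.copy(),
                         label_names=dict(labels_t1.label_names))
    if spec.noise_sd > 0:
        out_inten = out_inten + rng.normal(
            0.0, spec.noise_sd, out_inten.shape).astype(np.float32)
    volume_t2 = Volume(out_inten.astype(np.float32), labels_t1.spacing,
                       labels_t1.origin, labels_t1.direction.copy())
    return volume_t2, labels_t2, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class PlanDistribution:
    """Sampling ranges for per-subject surgical plans (uniform draws).

    Defaults mirror the magnitude of advancements reported for bimaxillary
    advancement cases: maxilla U[1, 5] mm, mandible U[5, 15] mm, soft/hard
    coupling U[0.7, 1.0], 0.5 mm soft-tissue jitter and a +/-2 degree /
    +/-2 mm nuisance head pose.
    """

    maxilla_advance_mm: tuple[float, float] = (1.0, 5.0)
    mandible_advance_mm: tuple[float, float] = (5.0, 15.0)
    soft_coupling: tuple[float, float] = (0.7, 1.0)
    soft_noise_sd_mm: float = 0.5
    head_rotation_deg: float = 2.0
    head_translation_mm: float = 2.0

    def validate(self) -> None:
        for name in ("maxilla_advance_mm", "mandible_advance_mm", "soft_coupling"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")

    def draw_plan(self, rng: np.random.Generator,
                  center_mm: tuple[float, float, float]) -> SurgicalPlan:
        coupling = rng.uniform(*self.soft_coupling)
        pose = RigidTransform(
            rotation_deg=tuple(rng.uniform(-self.head_rotation_deg,
                                           self.head_rotation_deg, 3)),
            translation_mm=tuple(rng.uniform(-self.head_translation_mm,
                                             self.head_translation_mm, 3)),
            center_mm=center_mm)
        return SurgicalPlan(
            maxilla_advance_mm=float(rng.uniform(*self.maxilla_advance_mm)),
            mandible_advance_mm=float(rng.uniform(*self.mandible_advance_mm)),
            head_pose=pose,
            soft_coupling_maxilla=coupling, soft_coupling_mandible=coupling,
            soft_noise_sd_mm=self.soft_noise_sd_mm)


@dataclass
class PhantomSubject:
    subject_id: str
    spec: PhantomSpec
    plan: SurgicalPlan
    volume_t1: Volume
    labels_t1: LabelMap
    volume_t2: Volume
    labels_t2: LabelMap
    ground_truth: dict[str, RigidTransform]


def make_cohort(n: int, spec: PhantomSpec | None = None,
                plan_distribution: PlanDistribution | None = None,
                seed: int = 0) -> list[PhantomSubject]:
    """Generate ``n`` independent subjects with recorded ground truth."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    spec = spec or PhantomSpec()
    dist = plan_distribution or PlanDistribution()
    dist.validate()
    extent = np.asarray(spec.grid_shape) * spec.spacing_mm
    center = tuple(extent / 2.0)
    subjects = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n)):
        child = np.random.default_rng(ss)
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        sub_spec = replace(spec, seed=sub_seed)
        vol1, lab1 = make_phantom(sub_spec)
        # plans are drawn conditional on the subject fitting the grid: a draw
        # whose pose/advancement pushes a piece outside is rejected and redrawn
        for attempt in range(20):
            plan = dist.draw_plan(child, center)
            try:
                vol2, lab2, truth = apply_surgery(vol1, lab1, plan,
                                                  spec=sub_spec,
                                                  seed=sub_seed + 1)
                break
            except ValueError:
                if attempt == 19:
                    raise
        subjects.append(PhantomSubject(f"subject_{i + 1:02d}", sub_spec, plan,
                                       vol1, lab1, vol2, lab2, truth))
    return subjects


def ground_truth_table(subjects: list[PhantomSubject]):
    """Cohort ground truth as a tidy DataFrame (one row per subject, piece)."""
    import pandas as pd

    rows = []
    for s in subjects:
        for piece, t in s.ground_truth.items():
            rows.append({"subject": s.subject_id, "piece": piece,
                         "rot_x_deg": t.rotation_deg[0],
                         "rot_y_deg": t.rotation_deg[1],
                         "rot_z_deg": t.rotation_deg[2],
                         "t_x_mm": t.translation_mm[0],
                         "t_y_mm": t.translation_mm[1],
                         "t_z_mm": t.translation_mm[2],
                         "center_x_mm": t.center_mm[0],
                         "center_y_mm": t.center_mm[1],
                         "center_z_mm": t.center_mm[2],
                         "maxilla_advance_mm": s.plan.maxilla_advance_mm,
                         "mandible_advance_mm": s.plan.mandible_advance_mm,
                         "coupling_maxilla": s.plan.soft_coupling_maxilla,
                         "coupling_mandible": s.plan.soft_coupling_mandible})
    return pd.DataFrame(rows)
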