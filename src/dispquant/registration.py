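"""Volumes, rigid transforms, and voxel-based rigid superimposition.

The pre/post-surgical scans (T1/T2) are aligned on the cranial base only:
the base is unaltered by orthognathic surgery, so maximising an intensity
similarity metric (mutual information) over cranial-base voxels recovers the
patient's change of head pose between acquisitions without being biased by
the surgical displacement of the jaws.  T1 is always the fixed (reference)
frame; the recovered transform maps T2 geometry into that frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3-D scalar grid in world millimetres.

    ``data`` is indexed ``[i, j, k]`` along world x/y/z; voxel ``(i, j, k)``
    has its centre at ``origin + (i, j, k) * spacing`` (identity direction).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-9):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape).astype(float)
        ijk = np.stack(idx, axis=-1)
        return ijk * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world coordinates of the outer voxel-centre box."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy(), direction=self.direction.copy())


@dataclass
class LabelMap(Volume):
    """Integer grid naming anatomical structures per voxel (0 = background)."""

    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map data must be an integer array")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    def value_of(self, label: int | str) -> int:
        if isinstance(label, str):
            for value, name in self.label_names.items():
                if name == label:
                    return value
            raise KeyError(f"label {label!r} not defined; known: {self.label_names}")
        return int(label)

    def mask(self, label: int | str) -> np.ndarray:
        return self.data == self.value_of(label)

    def copy(self) -> "LabelMap":
        return replace(self, data=self.data.copy(), direction=self.direction.copy(),
                       label_names=dict(self.label_names))


@dataclass(frozen=True)
class RigidTransform:
    """Rigid mapping ``p -> R (p - c) + c + t`` in world millimetres.

    ``rotation_deg`` are extrinsic x-y-z Euler angles (degrees), i.e.
    ``R = Rz @ Ry @ Rx`` — the "six degrees of freedom" of the
    superimposition: translation and rotation about each world axis.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    @property
    def offset(self) -> np.ndarray:
        """``b`` of the affine form ``p -> R p + b``."""
        c = np.asarray(self.center_mm)
        return c + np.asarray(self.translation_mm) - self.matrix @ c

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.offset

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.matrix.T

    @classmethod
    def from_affine(cls, matrix: np.ndarray, offset: np.ndarray,
                    center: tuple[float, float, float] = (0, 0, 0)) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        angles = Rotation.from_matrix(matrix).as_euler("xyz", degrees=True)
        c = np.asarray(center, dtype=float)
        t = np.asarray(offset, dtype=float) - c + matrix @ c
        return cls(tuple(angles), tuple(t), tuple(c))

    @classmethod
    def from_translation(cls, t: tuple[float, float, float]) -> "RigidTransform":
        return cls(translation_mm=tuple(float(v) for v in t))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (``other`` applied first)."""
        r = self.matrix @ other.matrix
        b = self.matrix @ other.offset + self.offset
        return RigidTransform.from_affine(r, b, self.center_mm)

    def inverse(self) -> "RigidTransform":
        r = self.matrix.T
        return RigidTransform.from_affine(r, -r @ self.offset, self.center_mm)

    def is_identity(self, tol: float = 0.0) -> bool:
        return (np.allclose(self.matrix, np.eye(3), atol=tol)
                and np.allclose(self.offset, 0.0, atol=tol))

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "convention": "extrinsic xyz; p -> R(p-c)+c+t; units mm/deg",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rotation_deg"]), tuple(d["translation_mm"]),
                   tuple(d.get("center_mm", (0, 0, 0))))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# SimpleITK interop
# --------------------------------------------------------------------------

def _to_sitk(volume: Volume, dtype=None) -> sitk.Image:
    data = volume.data if dtype is None else volume.data.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    img.SetDirection(tuple(volume.direction.ravel()))
    return img


def _from_sitk(img: sitk.Image, like: Volume | None = None) -> Volume:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    vol = Volume(data, img.GetSpacing(), img.GetOrigin(),
                 np.asarray(img.GetDirection()).reshape(3, 3))
    if isinstance(like, LabelMap):
        return LabelMap(vol.data.astype(like.data.dtype), vol.spacing, vol.origin,
                        vol.direction, label_names=dict(like.label_names))
    return vol


def _sitk_transform(t: RigidTransform) -> sitk.Euler3DTransform:
    tf = sitk.Euler3DTransform()
    tf.SetCenter((0.0, 0.0, 0.0))
    tf.SetMatrix(tuple(t.matrix.ravel()), 1e-8)
    tf.SetTranslation(tuple(t.offset))
    return tf


def _from_sitk_transform(tf) -> RigidTransform:
    if hasattr(tf, "Downcast"):
        tf = tf.Downcast()
    if isinstance(tf, sitk.CompositeTransform):
        tf = tf.GetNthTransform(tf.GetNumberOfTransforms() - 1).Downcast()
    et = sitk.Euler3DTransform(tf)
    r = np.asarray(et.GetMatrix()).reshape(3, 3)
    c = np.asarray(et.GetCenter())
    b = c + np.asarray(et.GetTranslation()) - r @ c
    return RigidTransform.from_affine(r, b)


# --------------------------------------------------------------------------
# resampling and transforming
# --------------------------------------------------------------------------

_INTERPOLATORS = {"trilinear": sitk.sitkLinear, "linear": sitk.sitkLinear,
                  "nearest": sitk.sitkNearestNeighbor}


def resample(volume: Volume, new_spacing_mm: float,
             interpolation: str = "trilinear") -> Volume:
    """Resample onto an isotropic grid of ``new_spacing_mm``.

    World-space extent is preserved within one voxel.  Scans are typically
    reformatted from their acquisition voxel size (0.4 mm) to the working
    resolution (0.5 mm) before superimposition.
    """
    if new_spacing_mm <= 0:
        raise ValueError(f"new spacing must be positive, got {new_spacing_mm}")
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if all(abs(s - new_spacing_mm) < 1e-12 for s in volume.spacing):
        return volume.copy()
    new_sp = (float(new_spacing_mm),) * 3
    size = [max(1, int(round(n * s / new_spacing_mm)))
            for n, s in zip(volume.shape, volume.spacing)]
    img = _to_sitk(volume, dtype=np.float32 if interpolation != "nearest" else None)
    out = sitk.Resample(img, size, sitk.Transform(), _INTERPOLATORS[interpolation],
                        volume.origin, new_sp, tuple(volume.direction.ravel()), 0.0,
                        img.GetPixelID())
    res = _from_sitk(out, like=volume)
    if not isinstance(volume, LabelMap):
        res.data = res.data.astype(volume.data.dtype, copy=False)
    return res


def apply_transform(obj, t: RigidTransform, interpolation: str | None = None):
    """Apply a rigid transform to a mesh, point array, volume or label map.

    Volumes are resampled onto their own grid under the mapping (labels with
    nearest-neighbour, intensities trilinear); meshes/points are mapped
    exactly, preserving all pairwise distances.
    """
    from .surface import SurfaceMesh  # local import to avoid a cycle

    if isinstance(obj, SurfaceMesh):
        return obj.transformed(t)
    if isinstance(obj, LabelMap):
        interp = interpolation or "nearest"
        img = _to_sitk(obj)
        out = sitk.Resample(img, img, _sitk_transform(t.inverse()),
                            _INTERPOLATORS[interp], 0)
        return _from_sitk(out, like=obj)
    if isinstance(obj, Volume):
        interp = interpolation or "trilinear"
        img = _to_sitk(obj, dtype=np.float32)
        out = sitk.Resample(img, img, _sitk_transform(t.inverse()),
                            _INTERPOLATORS[interp], 0.0)
        res = _from_sitk(out, like=obj)
        res.data = res.data.astype(obj.data.dtype, copy=False)
        return res
    return t.apply_points(np.asarray(obj, dtype=float))


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------

def mutual_information(a: Volume, b: Volume, mask: np.ndarray | None = None,
                       bins: int = 32) -> float:
    """Mutual information of two volumes over a voxel mask, in bits.

    The joint histogram uses ``bins`` equal-width bins per image spanning
    each image's own range over the mask.  MI(a, a) equals the histogram
    entropy of ``a``; MI is symmetric and non-negative.
    """
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape must match the volumes")
    if not mask.any():
        raise ValueError("mask is empty")
    x = a.data[mask].astype(float).ravel()
    y = b.data[mask].astype(float).ravel()
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


# --------------------------------------------------------------------------
# rigid registration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationConfig:
    """Settings of the voxel-based superimposition (recorded per output)."""

    bins: int = 32
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    sampling_fraction: float = 0.5
    sampling_seed: int = 12345
    max_iterations: int = 500
    restarts: int = 2
    #: crop both volumes to the mask's bounding box before optimising; the
    #: moving pad adds the expected capture range of the initial misalignment
    roi_pad_mm: float = 8.0
    capture_pad_mm: float = 12.0


@dataclass
class RegistrationResult:
    transform: RigidTransform  # maps moving (T2) geometry into fixed (T1) frame
    converged: bool
    final_metric: float        # optimizer metric (negated Mattes MI)
    final_mi_bits: float       # MI over the mask after alignment, in bits
    stop_description: str = ""
    settings: dict = field(default_factory=dict)


class RegistrationError(RuntimeError):
    pass


def _coarse_translation_search(fixed: Volume, moving: Volume,
                               mask: np.ndarray, cfg: "RegistrationConfig",
                               step_mm: float = 2.0) -> np.ndarray:
    """Exhaustive MI grid search over translations at coarse resolution.

    The slab-like mask makes the MI landscape a broad plateau with a sharp
    peak where internal structure aligns; a gradient optimizer started on
    the plateau can stall, so the best integer-step translation within the
    capture range seeds it instead.  Deterministic by construction.
    """
    from scipy.ndimage import gaussian_filter

    stride = max(1, int(round(step_mm / fixed.spacing[0])))
    f = gaussian_filter(fixed.data.astype(np.float32), stride / 2.0)
    m = gaussian_filter(moving.data.astype(np.float32), stride / 2.0)
    sub = (slice(None, None, stride),) * 3
    f, m, mk = f[sub], m[sub], mask[sub]
    idx = np.stack(np.nonzero(mk), axis=-1)
    if len(idx) == 0:  # stride skipped the whole mask; fall back to no shift
        return np.zeros(3)
    fvals = f[idx[:, 0], idx[:, 1], idx[:, 2]]
    off = np.round((np.asarray(moving.origin) - np.asarray(fixed.origin))
                   / (np.asarray(fixed.spacing) * stride)).astype(int)
    steps = int(np.ceil(cfg.capture_pad_mm / step_mm))
    grid = range(-steps, steps + 1)
    best, best_shift = -np.inf, np.zeros(3)
    bins = 16
    for sx in grid:
        for sy in grid:
            for sz in grid:
                j = idx + np.array([sx, sy, sz]) - off
                ok = np.all((j >= 0) & (j < np.asarray(m.shape)), axis=1)
                if ok.sum() < max(20, 0.5 * len(idx)):
                    continue
                mv = m[j[ok, 0], j[ok, 1], j[ok, 2]]
                joint, _, _ = np.histogram2d(fvals[ok], mv, bins=bins)
                p = joint / joint.sum()
                px = p.sum(1, keepdims=True)
                py = p.sum(0, keepdims=True)
                nz = p > 0
                mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
                if mi > best:
                    best, best_shift = mi, np.array([sx, sy, sz], float)
    # shift in voxel steps of the coarse grid -> world mm, moving relative
    # to fixed: moving content at fixed point x matches m(x + shift)
    return best_shift * stride * np.asarray(fixed.spacing)


def _run_once(fixed_img, moving_img, mask_img, cfg: RegistrationConfig,
              init: sitk.Euler3DTransform):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.bins)
    reg.SetMetricFixedMask(mask_img)
    if cfg.sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.sampling_seed)
    else:
        reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=cfg.max_iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-7)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(init, inPlace=False)
    out = reg.Execute(fixed_img, moving_img)
    return out, reg.GetMetricValue(), reg.GetOptimizerStopConditionDescription()


def register_rigid(fixed: Volume, moving: Volume, mask: np.ndarray | LabelMap,
                   config: RegistrationConfig | None = None,
                   mask_label: int | str | None = None) -> RegistrationResult:
    """Recover the 6-DOF rigid transform aligning ``moving`` to ``fixed``.

    Mutual information is maximised over ``mask`` voxels of the fixed image
    (the cranial-base label), so surgical change outside the mask cannot bias
    the fit.  The returned transform maps moving-frame geometry (meshes,
    points, volumes) into the fixed frame.  Non-convergence is retried from
    perturbed initialisations and, failing that, flagged on the result.
    """
    cfg = config or RegistrationConfig()
    if isinstance(mask, LabelMap):
        mask = mask.mask(mask_label if mask_label is not None else "cranial_base")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fixed.shape:
        raise ValueError("mask must be on the fixed grid")
    if not mask.any():
        raise ValueError("registration mask covers zero voxels")

    def _crop(vol: Volume, pad_mm: float) -> Volume:
        nz = np.nonzero(mask)
        pad = [int(np.ceil(pad_mm / s)) for s in vol.spacing]
        lo = [max(0, int(i.min()) - p) for i, p in zip(nz, pad)]
        hi = [min(n, int(i.max()) + p + 1)
              for i, n, p in zip(nz, vol.shape, pad)]
        sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        origin = tuple(np.asarray(vol.origin)
                       + np.asarray(lo) * np.asarray(vol.spacing))
        return Volume(sub, vol.spacing, origin, vol.direction)

    # the metric only looks at mask voxels of the fixed image, so both
    # volumes can be cropped to the mask neighbourhood without changing the
    # optimum; world coordinates (and hence the transform) are unaffected
    fixed_roi = _crop(fixed, cfg.roi_pad_mm)
    moving_roi = _crop(Volume(moving.data, moving.spacing, moving.origin,
                              moving.direction),
                       cfg.roi_pad_mm + cfg.capture_pad_mm)
    mask_roi = _crop(Volume(mask.astype(np.uint8), fixed.spacing, fixed.origin,
                            fixed.direction), cfg.roi_pad_mm)
    fixed_img = _to_sitk(fixed_roi, dtype=np.float32)
    moving_img = _to_sitk(moving_roi, dtype=np.float32)
    mask_img = _to_sitk(mask_roi)

    center = tuple(np.asarray(fixed_roi.origin)
                   + (np.asarray(fixed_roi.shape) - 1)
                   * np.asarray(fixed_roi.spacing) / 2.0)
    shift = _coarse_translation_search(fixed_roi, moving_roi,
                                       mask_roi.data.astype(bool), cfg)
    rng = np.random.default_rng(cfg.sampling_seed)
    best = None
    for attempt in range(cfg.restarts + 1):
        init = sitk.Euler3DTransform()
        init.SetCenter(center)
        init.SetTranslation(tuple(shift))
        if attempt > 0:  # restart from a small random perturbation
            init.SetRotation(*np.deg2rad(rng.uniform(-1, 1, 3)))
            init.SetTranslation(tuple(shift + rng.uniform(-1, 1, 3)))
        try:
            out, metric, stop = _run_once(fixed_img, moving_img, mask_img, cfg, init)
        except RuntimeError as exc:  # pragma: no cover - optimizer blow-up
            if attempt == cfg.restarts:
                raise RegistrationError(str(exc)) from exc
            continue
        converged = "Maximum number of iterations" not in stop
        if best is None or metric < best[1]:
            best = (out, metric, stop, converged)
        if converged:
            break

    out, metric, stop, converged = best
    sol = _from_sitk_transform(out)       # maps fixed points -> moving points
    geometric = sol.inverse()             # maps moving geometry -> fixed frame
    aligned = apply_transform(moving, geometric, interpolation="trilinear")
    # report MI over a slightly dilated mask so the bone-air interface (the
    # structure that actually drives the fit) contributes to the score
    from scipy.ndimage import binary_dilation
    mi_bits = mutual_information(fixed, aligned, binary_dilation(mask, iterations=3),
                                 bins=cfg.bins)
    return RegistrationResult(
        transform=geometric, converged=converged, final_metric=float(metric),
        final_mi_bits=mi_bits, stop_description=stop,
        settings={"metric": f"Mattes MI ({cfg.bins} bins)",
                  "optimizer": "regular-step gradient descent, multi-resolution",
                  "shrink_factors": list(cfg.shrink_factors),
                  "sampling_fraction": cfg.sampling_fraction,
                  "fixed_frame": "T1"})


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def save_nifti(volume: Volume, path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = volume.direction @ np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))


def load_nifti(path, as_labels: bool = False,
               label_names: dict[int, str] | None = None) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    data = np.asarray(img.dataobj)
    spacing = tuple(np.linalg.norm(affine[:3, i]) for i in range(3))
    direction = affine[:3, :3] / np.asarray(spacing)
    origin = tuple(affine[:3, 3])
    if as_labels:
        return LabelMap(np.rint(data).astype(np.int16), spacing, origin, direction,
                        label_names=label_names or {})
    return Volume(data, spacing, origin, direction)
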