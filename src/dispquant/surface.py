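"""Label map -> triangle mesh extraction and binary STL round-trip.

Each anatomical label (maxilla + upper teeth, mandible + lower teeth, soft
tissue) is exported as its own mesh so that downstream closest-point queries
can never match across structures.  Extraction is marching cubes at the 0.5
iso-level of the binarised label; by default the binary mask is first
anti-aliased with a small Gaussian (0.8 voxel sigma), which removes the
staircase area bias of binary marching cubes while leaving axis-aligned flat
faces exactly in plane (the smoothing kernel is symmetric about the face).
Set ``smooth_sigma_voxels=0`` for the raw binary surface.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from skimage import measure

from .registration import LabelMap, RigidTransform


class StlParseError(ValueError):
    """Malformed STL payload; carries the byte offset of the problem."""

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


@dataclass
class SurfaceMesh:
    """Labelled triangle mesh in world millimetres with outward normals."""

    vertices: np.ndarray          # (n, 3) float64, world mm
    faces: np.ndarray             # (m, 3) int, outward winding
    label: str = ""
    _tm: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces index vertices out of range")

    # ---- derived geometry ----------------------------------------------
    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return self._tm

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.trimesh.vertex_normals)

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.faces).tobytes())
        return h.hexdigest()[:16]

    def transformed(self, t: RigidTransform) -> "SurfaceMesh":
        return SurfaceMesh(t.apply_points(self.vertices), self.faces.copy(),
                           label=self.label)

    def drop_unreferenced_vertices(self) -> "SurfaceMesh":
        used = np.unique(self.faces)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(self.vertices[used], remap[self.faces], self.label)


def extract_surface(labels: LabelMap, label: int | str,
                    smooth_sigma_voxels: float = 0.8) -> SurfaceMesh:
    """Extract the closed surface of one label as a mesh in world mm."""
    value = labels.value_of(label)
    name = labels.label_names.get(value, str(value))
    mask = labels.data == value
    if not mask.any():
        raise ValueError(f"label {name!r} (value {value}) is absent or empty")

    # crop to the label's bounding box (plus margin) to keep marching cubes fast
    margin = max(3, int(np.ceil(3 * smooth_sigma_voxels)) + 1)
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - margin) for i in idx]
    hi = [min(s, int(i.max()) + margin + 1) for i, s in zip(idx, labels.shape)]
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float32)

    if smooth_sigma_voxels > 0:
        sub = gaussian_filter(sub, smooth_sigma_voxels)
    if sub.max() <= 0.5 or sub.min() >= 0.5:
        raise ValueError(f"label {name!r} is too small to carry an iso-surface")
    sp = labels.spacing
    verts, faces, _, _ = measure.marching_cubes(sub, level=0.5, spacing=sp)
    verts = verts + np.asarray(labels.origin) + np.asarray(lo) * np.asarray(sp)
    if np.any(labels.direction != np.eye(3)):
        verts = verts @ labels.direction.T  # pragma: no cover - identity in practice
    mesh = SurfaceMesh(verts, faces, label=name)
    if mesh.trimesh.volume < 0:  # ensure outward winding
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1], label=name)
    return mesh


# --------------------------------------------------------------------------
# binary STL I/O (little-endian, 80-byte header, float32), with JSON sidecar
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stl(mesh: SurfaceMesh, path, metadata: dict | None = None) -> None:
    """Write binary STL plus a sidecar JSON recording units and provenance.

    STL itself carries no units; this artifact fixes millimetres and writes
    the label and mesh checksum alongside.
    """
    if mesh.n_faces == 0:
        raise ValueError("refusing to write a mesh with zero triangles")
    path = Path(path)
    tris = mesh.triangles.astype("<f4")
    normals = np.asarray(
        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).face_normals,
        dtype="<f4")
    record = np.zeros(mesh.n_faces,
                      dtype=[("normal", "<f4", 3), ("verts", "<f4", (3, 3)),
                             ("attr", "<u2")])
    record["normal"] = normals
    record["verts"] = tris
    with open(path, "wb") as fh:
        fh.write(b"dispquant binary STL, units mm".ljust(80, b" "))
        fh.write(struct.pack("<I", mesh.n_faces))
        fh.write(record.tobytes())
    side = {"units": "mm", "label": mesh.label, "checksum": mesh.checksum(),
            "n_faces": mesh.n_faces, "n_vertices": mesh.n_vertices}
    side.update(metadata or {})
    _sidecar_path(path).write_text(json.dumps(side, indent=2))


def read_stl(path, label: str | None = None) -> SurfaceMesh:
    """Read a binary STL; duplicate vertices are welded exactly.

    Truncated or inconsistent payloads raise :class:`StlParseError` naming
    the byte offset at which the file stops making sense.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 84:
        raise StlParseError("file too short for an STL header", len(raw))
    if raw[:5] == b"solid" and b"facet" in raw[:400]:
        tm = trimesh.load(str(path), file_type="stl", process=False)  # ASCII STL
        verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    else:
        (n_faces,) = struct.unpack_from("<I", raw, 80)
        expected = 84 + 50 * n_faces
        if len(raw) < expected:
            raise StlParseError(
                f"triangle records truncated: header promises {n_faces} "
                f"triangles ({expected} bytes), file has {len(raw)}", len(raw))
        record = np.frombuffer(raw, offset=84, count=n_faces,
                               dtype=[("normal", "<f4", 3),
                                      ("verts", "<f4", (3, 3)), ("attr", "<u2")])
        tris = record["verts"].astype(np.float64)
        flat = tris.reshape(-1, 3)
        verts, inverse = np.unique(flat, axis=0, return_inverse=True)
        faces = inverse.reshape(-1, 3)
    if label is None:
        side = _sidecar_path(path)
        if side.exists():
            label = json.loads(side.read_text()).get("label", "")
    return SurfaceMesh(verts, faces, label=label or "")
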