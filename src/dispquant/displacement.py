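"""Region-restricted signed closest-point displacement between time points.

This is the heart of the method: instead of tracking landmarks, an operator
paints an *area* (a contiguous vertex patch) on the reference-frame mesh and
the displacement of the structure is summarised as the minimum / maximum /
mean of per-vertex closest-point distances to the same-label mesh at the
other time point.  Distances are signed by the source vertex's outward
normal: positive = outward (advancement), negative = inward.  Queries are
restricted to the mesh carrying the same anatomical label, so a lip vertex
can never be matched against teeth ("label firewall").

Closest points are exact: a KD-tree over triangle centroids provides a
provable candidate bound (centroid distance minus the triangle's bounding
radius never exceeds the true distance), and the exact point-to-triangle
minimum is taken over all candidates.  Equidistant triangles resolve to the
lowest triangle index for determinism.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .surface import SurfaceMesh

#: the 15 measurement areas: 4 hard-tissue, 11 soft-tissue
HARD_AREAS = ("A Point", "Upper Incisors", "Lower Incisors", "Pogonion")
SOFT_AREAS = ("Nasal Tip", "Soft A Point", "Upper Lip", "Left Cheilion",
              "Right Cheilion", "Left Supra Cheilion", "Right Supra Cheilion",
              "Left Sub Cheilion", "Right Sub Cheilion", "Lower Lip",
              "Soft Pogonion")
AREA_NAMES = HARD_AREAS + SOFT_AREAS


class LabelMismatchError(ValueError):
    """Raised when a query would cross anatomical labels."""


class ChecksumMismatchError(ValueError):
    """Raised when a region is applied to a mesh it was not painted on."""


class SignMixingWarning(UserWarning):
    """A region mixes inward and outward displacement; its signed mean
    underestimates the true change (the reason curved nasal-base areas are
    excluded from this kind of analysis)."""


# --------------------------------------------------------------------------
# exact point-to-triangle closest points (Ericson's region decomposition)
# --------------------------------------------------------------------------

def closest_point_on_triangles(points: np.ndarray, tri_a: np.ndarray,
                               tri_b: np.ndarray, tri_c: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle (a, b, c) from each query point.

    All inputs are ``(k, 3)``; element ``i`` pairs ``points[i]`` with
    triangle ``i``.  Face, edge and vertex cases are all handled.
    """
    p = np.asarray(points, dtype=float)
    a, b, c = (np.asarray(t, dtype=float) for t in (tri_a, tri_b, tri_c))
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        mask = mask & ~done
        if mask.any():
            out[mask] = value[mask] if value.ndim == 2 else value
            done[mask] = True

    settle((d1 <= 0) & (d2 <= 0), a)                      # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                     # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)                     # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)[:, None]
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab * ab)      # edge AB
        v_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)[:, None]
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + v_ac * ac)      # edge AC
        num, den = d4 - d3, (d4 - d3) + (d5 - d6)
        v_bc = np.where(den != 0, num / den, 0.0)[:, None]
        settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
               b + v_bc * (c - b))                                    # edge BC
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = (vb / denom)[:, None]
        w = (vc / denom)[:, None]
        settle(np.ones(len(p), dtype=bool), a + v * ab + w * ac)      # interior
    return out


class TriangleProximity:
    """Exact nearest-triangle queries against one target mesh.

    The candidate search is pruned with a KD-tree over triangle centroids:
    any triangle whose centroid lies farther than ``upper_bound +
    bounding_radius`` cannot contain the closest point, so the exact
    point-to-triangle minimum over the remaining candidates is the global
    minimum.
    """

    def __init__(self, mesh: SurfaceMesh):
        if mesh.n_faces == 0:
            raise ValueError("target mesh has no triangles")
        self.mesh = mesh
        tris = mesh.triangles
        self._a = np.ascontiguousarray(tris[:, 0])
        self._b = np.ascontiguousarray(tris[:, 1])
        self._c = np.ascontiguousarray(tris[:, 2])
        self._centroids = tris.mean(axis=1)
        self._radii = np.linalg.norm(
            tris - self._centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radii.max())
        self._tree = cKDTree(self._centroids)

    def _exact(self, pts: np.ndarray, tri_idx: np.ndarray,
               pt_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cp = closest_point_on_triangles(pts[pt_idx], self._a[tri_idx],
                                        self._b[tri_idx], self._c[tri_idx])
        return np.linalg.norm(cp - pts[pt_idx], axis=1), cp

    def query(self, points: np.ndarray, chunk: int = 4096,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(distance, closest_point, triangle_id)`` per query point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        dist = np.empty(n)
        cpts = np.empty((n, 3))
        tids = np.empty(n, dtype=np.int64)
        m = len(self._a)
        for s in range(0, n, chunk):
            block = pts[s:s + chunk]
            nb = len(block)
            if m <= 512:  # small mesh: brute force all pairs
                pi = np.repeat(np.arange(nb), m)
                ti = np.tile(np.arange(m), nb)
            else:
                k = min(8, m)
                _, near = self._tree.query(block, k=k)
                near = near.reshape(nb, -1)
                pi0 = np.repeat(np.arange(nb), near.shape[1])
                d0, _ = self._exact(block, near.ravel(), pi0)
                ub = d0.reshape(nb, -1).min(axis=1)
                lists = self._tree.query_ball_point(
                    block, ub + self._rmax + 1e-9)
                counts = np.fromiter((len(l) for l in lists), dtype=np.int64,
                                     count=nb)
                pi = np.repeat(np.arange(nb), counts)
                ti = np.fromiter((t for l in lists for t in l), dtype=np.int64,
                                 count=int(counts.sum()))
            d, cp = self._exact(block, ti, pi)
            order = np.lexsort((ti, d, pi))   # per point: min dist, lowest index
            pi_sorted = pi[order]
            first = np.ones(len(order), dtype=bool)
            first[1:] = pi_sorted[1:] != pi_sorted[:-1]
            sel = order[first]
            rows = pi[sel]
            dist[s + rows] = d[sel]
            cpts[s + rows] = cp[sel]
            tids[s + rows] = ti[sel]
        return dist, cpts, tids


def closest_point_distance(query: np.ndarray, target: SurfaceMesh,
                           ) -> tuple[float, np.ndarray, int]:
    """Exact distance from one world point to a mesh's triangle set."""
    d, cp, t = TriangleProximity(target).query(np.asarray(query, dtype=float))
    return float(d[0]), cp[0], int(t[0])


# --------------------------------------------------------------------------
# regions ("surface paint areas")
# --------------------------------------------------------------------------

@dataclass
class Region:
    """Named vertex patch on one labelled mesh."""

    name: str
    label: str
    vertex_ids: np.ndarray
    definition: dict = field(default_factory=dict)
    mesh_checksum: str = ""

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64).ravel()
        if len(self.vertex_ids) == 0:
            raise ValueError(f"region {self.name!r} is empty")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)


def _geodesic_distances(mesh: SurfaceMesh, source_vertex: int) -> np.ndarray:
    edges = mesh.trimesh.edges_unique
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]]
                             - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    graph = coo_matrix((np.r_[lengths, lengths],
                        (np.r_[edges[:, 0], edges[:, 1]],
                         np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n))
    return dijkstra(graph.tocsr(), directed=False, indices=source_vertex)


def paint_region(mesh: SurfaceMesh, seed_point, radius_mm: float,
                 metric: str = "euclidean", name: str = "region",
                 seed_tolerance_mm: float = 2.0) -> Region:
    """Paint a patch: all vertices within ``radius_mm`` of the seed's nearest
    vertex, under the chosen metric (straight-line or along-surface)."""
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if metric not in ("euclidean", "geodesic"):
        raise ValueError(f"unknown metric {metric!r}")
    seed = np.asarray(seed_point, dtype=float)
    surf_dist, _, _ = closest_point_distance(seed, mesh)
    if surf_dist > seed_tolerance_mm:
        raise ValueError(f"seed point {seed.tolist()} is {surf_dist:.2f} mm "
                         f"from the {mesh.label or 'target'} surface "
                         f"(> {seed_tolerance_mm} mm)")
    tree = cKDTree(mesh.vertices)
    _, seed_vertex = tree.query(seed)
    if metric == "euclidean":
        ids = tree.query_ball_point(mesh.vertices[seed_vertex],
                                    radius_mm + 1e-12)
        ids = np.sort(np.asarray(ids, dtype=np.int64))
    else:
        geo = _geodesic_distances(mesh, int(seed_vertex))
        ids = np.nonzero(geo <= radius_mm + 1e-12)[0]
    if len(ids) == 0:  # unreachable: the seed vertex itself is at distance 0
        raise ValueError(f"region {name!r} came out empty")
    return Region(name=name, label=mesh.label, vertex_ids=ids,
                  definition={"seed_point": seed.tolist(),
                              "radius_mm": float(radius_mm), "metric": metric},
                  mesh_checksum=mesh.checksum())


def region_from_vertex_ids(mesh: SurfaceMesh, name: str,
                           vertex_ids) -> Region:
    """Explicit paint set, e.g. an outline-following patch around the lips."""
    ids = np.asarray(vertex_ids, dtype=np.int64)
    if len(ids) and (ids.min() < 0 or ids.max() >= mesh.n_vertices):
        raise ValueError("vertex ids out of range for this mesh")
    return Region(name=name, label=mesh.label, vertex_ids=np.sort(ids),
                  definition={"explicit_ids": True},
                  mesh_checksum=mesh.checksum())


# --------------------------------------------------------------------------
# signed displacement and summaries
# --------------------------------------------------------------------------

@dataclass
class DisplacementSummary:
    region_name: str
    n_vertices: int
    min_mm: float
    max_mm: float
    mean_mm: float
    unsigned_mean_mm: float
    negative_fraction: float

    def to_dict(self) -> dict:
        return {"Region": self.region_name, "N": self.n_vertices,
                "Min": self.min_mm, "Max": self.max_mm, "Mean": self.mean_mm,
                "UnsignedMean": self.unsigned_mean_mm,
                "NegativeFraction": self.negative_fraction}


def signed_displacements(source_mesh: SurfaceMesh, vertex_ids,
                         target: SurfaceMesh | TriangleProximity) -> np.ndarray:
    """Signed closest-point displacement of selected source vertices.

    Magnitude is the exact closest-point distance to the target mesh; the
    sign is that of the dot product of (closest point - vertex) with the
    vertex's outward normal, ties (zero dot) resolving positive.
    """
    prox = target if isinstance(target, TriangleProximity) \
        else TriangleProximity(target)
    ids = np.asarray(vertex_ids, dtype=np.int64)
    verts = source_mesh.vertices[ids]
    normals = source_mesh.vertex_normals[ids]
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-12):
        bad = ids[norms < 1e-12]
        raise ValueError(f"degenerate outward normal at vertices {bad[:5]}")
    dist, cp, _ = prox.query(verts)
    dots = np.einsum("ij,ij->i", cp - verts, normals)
    return np.where(dots < 0, -dist, dist)


def _check_pair(region: Region | None, source: SurfaceMesh, target: SurfaceMesh):
    if source.label != target.label:
        raise LabelMismatchError(
            f"refusing cross-label query: source mesh is "
            f"{source.label!r}, target mesh is {target.label!r}")
    if region is not None:
        if region.label != source.label:
            raise LabelMismatchError(
                f"region {region.name!r} was painted on {region.label!r} but "
                f"the source mesh is {source.label!r}")
        if region.mesh_checksum and region.mesh_checksum != source.checksum():
            raise ChecksumMismatchError(
                f"region {region.name!r} is bound to a different mesh "
                f"(checksum {region.mesh_checksum}, source {source.checksum()})")


def _summarise(name: str, signed: np.ndarray,
               warn_sign_mixing: bool = True) -> DisplacementSummary:
    neg = float(np.mean(signed < 0))
    if warn_sign_mixing and 0.05 < neg < 0.95:
        warnings.warn(
            f"region {name!r} mixes inward and outward displacement "
            f"(negative fraction {neg:.2f}); its signed mean underestimates "
            f"the change", SignMixingWarning, stacklevel=3)
    return DisplacementSummary(
        region_name=name, n_vertices=len(signed),
        min_mm=float(signed.min()), max_mm=float(signed.max()),
        mean_mm=float(signed.mean()),
        unsigned_mean_mm=float(np.abs(signed).mean()),
        negative_fraction=neg)


def region_summary(region: Region, source_mesh: SurfaceMesh,
                   target_mesh: SurfaceMesh | None = None,
                   proximity: TriangleProximity | None = None,
                   warn_sign_mixing: bool = True) -> DisplacementSummary:
    """Min / max / mean signed displacement over one painted region."""
    if proximity is not None:
        target_mesh = proximity.mesh
    _check_pair(region, source_mesh, target_mesh)
    signed = signed_displacements(source_mesh, region.vertex_ids,
                                  proximity or target_mesh)
    return _summarise(region.name, signed, warn_sign_mixing)


def full_surface_summary(source_mesh: SurfaceMesh, target_mesh: SurfaceMesh,
                         warn_sign_mixing: bool = False) -> DisplacementSummary:
    """Summary over *every* source vertex (the 100%-area measurement).

    Useful only as a diagnostic: where the two surfaces overlap the
    per-vertex distances are near zero, so the full-surface mean grossly
    underestimates a rigid advancement.
    """
    _check_pair(None, source_mesh, target_mesh)
    signed = signed_displacements(source_mesh,
                                  np.arange(source_mesh.n_vertices),
                                  target_mesh)
    return _summarise("full_surface", signed, warn_sign_mixing)


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def save_regions(regions: list[Region], path) -> None:
    payload = [{"name": r.name, "label": r.label,
                "definition": r.definition,
                "vertex_ids": r.vertex_ids.tolist(),
                "mesh_checksum": r.mesh_checksum} for r in regions]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_regions(path) -> list[Region]:
    payload = json.loads(Path(path).read_text())
    return [Region(name=d["name"], label=d["label"],
                   vertex_ids=np.asarray(d["vertex_ids"], dtype=np.int64),
                   definition=d.get("definition", {}),
                   mesh_checksum=d.get("mesh_checksum", "")) for d in payload]


def summaries_to_frame(summaries: list[DisplacementSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def save_summaries(summaries: list[DisplacementSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def save_vertex_displacements(vertex_ids, signed_mm, path) -> None:
    """Per-vertex export for colour mapping (vertex_id, signed_mm)."""
    pd.DataFrame({"vertex_id": np.asarray(vertex_ids, dtype=np.int64),
                  "signed_mm": np.asarray(signed_mm, dtype=float)}
                 ).to_csv(path, index=False)
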