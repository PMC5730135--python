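"""Region painting and signed closest-point displacement (the core method)."""

import numpy as np
import pytest
import trimesh

import dispquant as dq
from dispquant.displacement import (ChecksumMismatchError, LabelMismatchError,
                                    SignMixingWarning,
                                    closest_point_on_triangles)


def brute_force_distances(points, mesh):
    """Exhaustive all-triangles oracle for closest-point distances."""
    tris = mesh.triangles
    out = np.empty(len(points))
    cps = np.empty((len(points), 3))
    for i, p in enumerate(points):
        rep = np.repeat(p[None], len(tris), axis=0)
        cp = closest_point_on_triangles(rep, tris[:, 0], tris[:, 1],
                                        tris[:, 2])
        d = np.linalg.norm(cp - rep, axis=1)
        j = int(np.argmin(d))
        out[i], cps[i] = d[j], cp[j]
    return out, cps


@pytest.fixture(scope="module")
def ico_mesh():
    sph = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    return dq.SurfaceMesh(np.asarray(sph.vertices), np.asarray(sph.faces),
                          label="soft_tissue")


class TestClosestPoint:
    def test_matches_brute_force_oracle(self, ico_mesh):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-15, 15, (200, 3))
        d, _, _ = dq.TriangleProximity(ico_mesh).query(pts)
        oracle, _ = brute_force_distances(pts, ico_mesh)
        assert np.max(np.abs(d - oracle)) < 1e-9

    def test_point_on_surface_has_zero_distance(self, ico_mesh):
        v = ico_mesh.vertices[17]
        d, cp, _ = dq.closest_point_distance(v, ico_mesh)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_height_above_flat_face(self, box_jaw_mesh):
        # anterior face is the plane y = 30; query 4 mm above its interior
        d, cp, _ = dq.closest_point_distance((32.0, 34.0, 32.0), box_jaw_mesh)
        assert d == pytest.approx(4.0, abs=1e-9)
        assert cp[1] == pytest.approx(30.0, abs=1e-9)

    def test_equidistant_tie_resolves_to_lowest_triangle(self):
        verts = np.array([[0, -1, 0], [1, -1, 0], [0, -1, 1],     # tri 0
                          [0, 1, 0], [1, 1, 0], [0, 1, 1]], float)  # tri 1
        mesh = dq.SurfaceMesh(verts, [[0, 1, 2], [3, 4, 5]])
        _, _, tri = dq.closest_point_distance((0.2, 0.0, 0.2), mesh)
        assert tri == 0

    def test_empty_mesh_rejected(self):
        empty = dq.SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="no triangles"):
            dq.TriangleProximity(empty)


class TestPaintRegion:
    def test_radius_zero_selects_single_nearest_vertex(self, ico_mesh):
        seed = ico_mesh.vertices[5] * 1.01
        region = dq.paint_region(ico_mesh, seed, 0.0)
        assert region.vertex_ids.tolist() == [5]

    def test_radius_beyond_diameter_selects_everything(self, ico_mesh):
        region = dq.paint_region(ico_mesh, ico_mesh.vertices[0], 100.0)
        assert region.n_vertices == ico_mesh.n_vertices

    def test_geodesic_patch_smaller_than_euclidean(self, sphere_mesh):
        """On a sphere the chord is shorter than the arc, so a geodesic
        radius covers strictly fewer vertices than the same euclidean radius."""
        seed = sphere_mesh.vertices[np.argmax(sphere_mesh.vertices[:, 2])]
        geo = dq.paint_region(sphere_mesh, seed, 10.0, metric="geodesic")
        euc = dq.paint_region(sphere_mesh, seed, 10.0, metric="euclidean")
        assert 0 < geo.n_vertices < euc.n_vertices

    def test_geodesic_distance_matches_graph_oracle(self, ico_mesh):
        import networkx as nx

        seed_vertex = 3
        region = dq.paint_region(ico_mesh, ico_mesh.vertices[seed_vertex], 6.0,
                                 metric="geodesic")
        g = nx.Graph()
        for a, b in ico_mesh.trimesh.edges_unique:
            g.add_edge(int(a), int(b), weight=float(np.linalg.norm(
                ico_mesh.vertices[a] - ico_mesh.vertices[b])))
        lengths = nx.single_source_dijkstra_path_length(g, seed_vertex)
        expected = sorted(v for v, d in lengths.items() if d <= 6.0 + 1e-12)
        assert region.vertex_ids.tolist() == expected

    def test_seed_far_from_surface_rejected(self, ico_mesh):
        with pytest.raises(ValueError, match="from the"):
            dq.paint_region(ico_mesh, (30.0, 0.0, 0.0), 5.0)

    def test_explicit_vertex_list_region(self, ico_mesh):
        region = dq.region_from_vertex_ids(ico_mesh, "lip outline", [4, 8, 15])
        assert region.n_vertices == 3
        with pytest.raises(ValueError, match="out of range"):
            dq.region_from_vertex_ids(ico_mesh, "bad", [10**6])


class TestSignedDisplacement:
    def test_outward_advancement_positive(self, box_jaw_mesh,
                                          advanced_box_jaw):
        region = dq.paint_region(box_jaw_mesh, (32, 30, 32), 8.0, name="ant")
        signed = dq.signed_displacements(box_jaw_mesh, region.vertex_ids,
                                         advanced_box_jaw)
        assert np.allclose(signed, 5.0, atol=1e-9)

    def test_inward_setback_negative(self, box_jaw_mesh):
        setback = box_jaw_mesh.transformed(
            dq.RigidTransform.from_translation((0, -3, 0)))
        region = dq.paint_region(box_jaw_mesh, (32, 30, 32), 8.0, name="ant")
        signed = dq.signed_displacements(box_jaw_mesh, region.vertex_ids,
                                         setback)
        assert np.allclose(signed, -3.0, atol=1e-9)

    def test_sign_agrees_with_inside_outside_oracle(self, sphere_mesh):
        """The normal-dot sign convention must agree with classifying the
        closest point as inside/outside the source solid.  For a sphere
        centred at the origin, membership is analytic: ||cp|| < radius."""
        t = dq.RigidTransform((4.0, -3.0, 2.0), (1.7, 0.6, -0.9), (0, 0, 0))
        target = sphere_mesh.transformed(t)
        ids = np.arange(0, sphere_mesh.n_vertices, 29)
        signed = dq.signed_displacements(sphere_mesh, ids, target)
        _, cps, _ = dq.TriangleProximity(target).query(sphere_mesh.vertices[ids])
        r = np.linalg.norm(cps, axis=1)
        clear = (np.abs(signed) > 0.05) & (np.abs(r - 20.0) > 0.2)
        assert clear.sum() > 50
        assert np.array_equal(signed[clear] < 0, (r < 20.0)[clear])


class TestRegionSummary:
    def test_identical_meshes_give_zero_summary(self, box_jaw_mesh):
        region = dq.paint_region(box_jaw_mesh, (32, 30, 32), 8.0, name="ant")
        s = dq.region_summary(region, box_jaw_mesh, box_jaw_mesh)
        assert (s.min_mm, s.max_mm, s.mean_mm) == (0.0, 0.0, 0.0)
        assert s.negative_fraction == 0.0

    def test_flat_face_advancement_reads_exactly(self, box_jaw_mesh,
                                                 advanced_box_jaw):
        region = dq.paint_region(box_jaw_mesh, (32, 30, 32), 8.0, name="ant")
        s = dq.region_summary(region, box_jaw_mesh, advanced_box_jaw)
        assert s.min_mm == pytest.approx(5.0, abs=0.05)
        assert s.max_mm == pytest.approx(5.0, abs=0.05)
        assert s.mean_mm == pytest.approx(5.0, abs=0.05)

    def test_oblique_translation_matches_per_vertex_oracle(self, ico_mesh):
        t = dq.RigidTransform.from_translation((2.0, 3.0, -1.0))
        target = ico_mesh.transformed(t)
        region = dq.paint_region(ico_mesh, ico_mesh.vertices[0], 5.0,
                                 name="ridge")
        s = dq.region_summary(region, ico_mesh, target, warn_sign_mixing=False)
        dists, cps = brute_force_distances(
            ico_mesh.vertices[region.vertex_ids], target)
        normals = ico_mesh.vertex_normals[region.vertex_ids]
        dots = np.einsum("ij,ij->i",
                         cps - ico_mesh.vertices[region.vertex_ids], normals)
        oracle = np.where(dots < 0, -dists, dists)
        assert s.min_mm == oracle.min()
        assert s.max_mm == oracle.max()
        assert s.mean_mm == pytest.approx(oracle.mean(), abs=1e-12)

    def test_rigid_motion_equivariance(self, box_jaw_mesh, advanced_box_jaw):
        region = dq.paint_region(box_jaw_mesh, (32, 30, 32), 6.0, name="ant")
        base = dq.region_summary(region, box_jaw_mesh, advanced_box_jaw)
        t = dq.RigidTransform((12.0, -7.0, 23.0), (4.0, -8.0, 15.0),
                              (30, 30, 30))
        src = box_jaw_mesh.transformed(t)
        dst = advanced_box_jaw.transformed(t)
        moved_region = dq.region_from_vertex_ids(src, "ant", region.vertex_ids)
        moved = dq.region_summary(moved_region, src, dst)
        assert moved.mean_mm == pytest.approx(base.mean_mm, abs=1e-6)
        assert moved.min_mm == pytest.approx(base.min_mm, abs=1e-6)
        assert moved.max_mm == pytest.approx(base.max_mm, abs=1e-6)

    def test_growing_region_past_edges_shrinks_mean(self, box_jaw_mesh,
                                                    advanced_box_jaw):
        """The 100%-area pitfall: enlarging the painted area into overlapping
        faces dilutes the mean displacement."""
        means = []
        for radius in (8.0, 25.0, 60.0):
            region = dq.paint_region(box_jaw_mesh, (32, 30, 32), radius,
                                     name="grow")
            s = dq.region_summary(region, box_jaw_mesh, advanced_box_jaw,
                                  warn_sign_mixing=False)
            means.append(abs(s.mean_mm))
        assert means[0] == pytest.approx(5.0, abs=0.05)
        assert means[0] > means[1] > means[2]

    def test_label_firewall(self, box_jaw_mesh, ico_mesh):
        region = dq.paint_region(ico_mesh, ico_mesh.vertices[0], 5.0,
                                 name="soft patch")
        assert region.label == "soft_tissue"
        with pytest.raises(LabelMismatchError):
            dq.region_summary(region, ico_mesh, box_jaw_mesh)
        with pytest.raises(LabelMismatchError):
            dq.region_summary(region, box_jaw_mesh, box_jaw_mesh)
        with pytest.raises(LabelMismatchError):
            dq.full_surface_summary(ico_mesh, box_jaw_mesh)

    def test_checksum_binds_region_to_its_mesh(self, ico_mesh):
        region = dq.paint_region(ico_mesh, ico_mesh.vertices[0], 5.0)
        other = dq.SurfaceMesh(ico_mesh.vertices * 1.001, ico_mesh.faces,
                               label=ico_mesh.label)
        with pytest.raises(ChecksumMismatchError):
            dq.region_summary(region, other, ico_mesh)

    def test_sign_mixing_emits_warning(self, ico_mesh):
        target = ico_mesh.transformed(
            dq.RigidTransform.from_translation((0.8, 0, 0)))
        region = dq.region_from_vertex_ids(ico_mesh, "whole",
                                           np.arange(ico_mesh.n_vertices))
        with pytest.warns(SignMixingWarning):
            dq.region_summary(region, ico_mesh, target)


def test_region_json_roundtrip(ico_mesh, tmp_path):
    regions = [dq.paint_region(ico_mesh, ico_mesh.vertices[0], 4.0, name="a"),
               dq.region_from_vertex_ids(ico_mesh, "b", [1, 2, 3])]
    path = tmp_path / "regions.json"
    dq.save_regions(regions, path)
    back = dq.load_regions(path)
    for orig, re in zip(regions, back):
        assert re.name == orig.name
        assert re.label == orig.label
        assert np.array_equal(re.vertex_ids, orig.vertex_ids)
        assert re.mesh_checksum == orig.mesh_checksum


def test_summary_csv_layout(ico_mesh, tmp_path):
    import pandas as pd

    region = dq.paint_region(ico_mesh, ico_mesh.vertices[0], 4.0, name="a")
    s = dq.region_summary(region, ico_mesh, ico_mesh)
    path = tmp_path / "summary.csv"
    dq.save_summaries([s], path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["Region", "N", "Min", "Max", "Mean",
                                "UnsignedMean", "NegativeFraction"]
    assert df.loc[0, "Region"] == "a"
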