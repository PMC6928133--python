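"""Synthetic atrium generation, monolayer extrusion and geodesic paths."""

import networkx as nx
import numpy as np
import pytest
import trimesh

from vablate import (
    SurfaceMesh,
    SyntheticLAParams,
    extrude_monolayer,
    generate_synthetic_la,
    geodesic_path,
    rectangular_strip,
)
from vablate.geometry import (
    LANDMARK_NAMES,
    MeshValidationError,
    PathError,
    path_length,
)
from vablate import io as vio


class TestSyntheticLA:
    def test_deterministic_for_fixed_seed(self):
        a = generate_synthetic_la(SyntheticLAParams(random_seed=7))
        b = generate_synthetic_la(SyntheticLAParams(random_seed=7))
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.triangles, b.triangles)

    def test_different_seeds_differ(self):
        a = generate_synthetic_la(SyntheticLAParams(random_seed=1))
        b = generate_synthetic_la(SyntheticLAParams(random_seed=2))
        assert a.vertices.shape != b.vertices.shape or not np.allclose(
            a.vertices[: min(len(a.vertices), len(b.vertices))],
            b.vertices[: min(len(a.vertices), len(b.vertices))],
        )

    def test_node_count_within_tolerance(self):
        mesh = generate_synthetic_la(
            SyntheticLAParams(target_node_count=2000, random_seed=3)
        )
        assert 1600 <= mesh.n_vertices <= 2400

    def test_euler_characteristic_five_holes(self, la_surface):
        # sphere with 5 open disks removed: chi = 2 - 5
        assert la_surface.euler_characteristic() == -3

    def test_all_landmarks_resolved_and_connected(self, la_surface):
        assert set(LANDMARK_NAMES) <= set(la_surface.landmark_sets)
        la_surface.validate()  # raises on empty/disconnected sets

    def test_infeasible_openings_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_synthetic_la(SyntheticLAParams(annulus_radius=40.0))

    def test_adjacency_symmetric_nonnegative(self, la_mesh):
        w = la_mesh.adjacency
        assert (w != w.T).nnz == 0
        assert w.data.min() >= 0.0


class TestMonolayer:
    def test_default_thickness_and_prism_count(self, la_surface, la_mesh):
        assert la_mesh.thickness == pytest.approx(1.89)
        assert la_mesh.n_prisms == la_surface.n_triangles

    def test_node_area_partition(self, la_surface, la_mesh):
        total_tri = la_surface.triangle_areas().sum()
        assert la_mesh.node_area.sum() == pytest.approx(total_tri, rel=1e-6)

    def test_shell_volume_on_coarse_sphere(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        surf = SurfaceMesh(np.asarray(sph.vertices), np.asarray(sph.faces), {})
        mono = extrude_monolayer(surf, thickness=1.89)
        assert mono.shell_volume() == pytest.approx(
            surf.triangle_areas().sum() * 1.89, rel=1e-12
        )
        # the extruded shell volume approximates the analytic spherical shell
        analytic = 4.0 / 3.0 * np.pi * (10.0 + 1.89) ** 3 - 4.0 / 3.0 * np.pi * 10.0 ** 3
        assert mono.shell_volume() == pytest.approx(analytic, rel=0.25)

    def test_annulus_flagged_nonconductive(self, la_surface, la_mesh):
        ann = la_surface.landmark_sets["mitral_annulus"]
        assert la_mesh.nonconductive_mask[ann].all()
        assert not la_mesh.nonconductive_mask[~np.isin(
            np.arange(la_mesh.n_nodes), ann
        )].any()

    def test_degenerate_triangle_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]], float)
        tris = np.array([[0, 1, 2], [0, 1, 3]])  # first triangle collinear
        surf = SurfaceMesh(verts, tris, {})
        with pytest.raises(MeshValidationError, match=r"\[0\]"):
            extrude_monolayer(surf, validate=False)

    def test_positive_thickness_required(self, la_surface):
        with pytest.raises(ValueError):
            extrude_monolayer(la_surface, thickness=0.0)


class TestGeodesics:
    def test_identity_path(self, small_strip):
        assert geodesic_path(small_strip, 5, 5) == [5]
        assert path_length(small_strip, [5]) == 0.0

    def test_matches_networkx_dijkstra(self, small_strip):
        surf = small_strip.surface
        g = nx.Graph()
        e = surf.edges()
        for i, j in e:
            g.add_edge(
                int(i), int(j),
                weight=float(np.linalg.norm(surf.vertices[i] - surf.vertices[j])),
            )
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.integers(0, surf.n_vertices, 2)
            ours = path_length(small_strip, geodesic_path(small_strip, int(a), int(b)))
            ref = nx.shortest_path_length(g, int(a), int(b), weight="weight")
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_blocked_band_disconnects(self):
        strip = rectangular_strip(20.0, 8.0, 1.0)
        x = strip.surface.vertices[:, 0]
        strip.nonconductive_mask[(x > 9.0) & (x < 11.5)] = True
        src = int(np.argmin(x))
        dst = int(np.argmax(x))
        with pytest.raises(PathError):
            geodesic_path(strip, src, dst)


class TestMeshIO:
    def test_ply_roundtrip_preserves_structure(self, la_surface, tmp_path):
        p = vio.save_surface_mesh(la_surface, tmp_path / "la.ply")
        spec = {k: v.tolist() for k, v in la_surface.landmark_sets.items()}
        back = vio.load_surface_mesh(p, spec)
        assert back.n_vertices == la_surface.n_vertices
        assert back.n_triangles == la_surface.n_triangles
        for name in LANDMARK_NAMES:
            assert np.array_equal(back.landmark_sets[name], la_surface.landmark_sets[name])

    def test_icosphere_with_seed_points(self, tmp_path):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=20.0)
        path = tmp_path / "sphere.stl"
        sph.export(str(path))
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(8, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        spec = {name: (20.0 * d).tolist() for name, d in zip(LANDMARK_NAMES, dirs)}
        mesh = vio.load_surface_mesh(path, spec)
        assert len(mesh.landmark_sets) == 8
        for name in LANDMARK_NAMES:
            assert len(mesh.landmark_sets[name]) >= 1

    def test_missing_landmark_named_in_error(self, la_surface, tmp_path):
        p = vio.save_surface_mesh(la_surface, tmp_path / "la.ply")
        spec = {k: v.tolist() for k, v in la_surface.landmark_sets.items()}
        del spec["roof_apex"]
        with pytest.raises(MeshValidationError, match="roof_apex"):
            vio.load_surface_mesh(p, spec)

    def test_unreadable_file_raises(self):
        with pytest.raises(FileNotFoundError):
            vio.load_surface_mesh("/nonexistent/mesh.stl", {})

    def test_vtk_legacy_roundtrip(self, tmp_path):
        # hand-written legacy file with two triangles
        text = (
            "# vtk DataFile Version 3.0\nsheet\nASCII\nDATASET POLYDATA\n"
            "POINTS 4 float\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n"
            "POLYGONS 2 8\n3 0 1 2\n3 0 2 3\n"
        )
        p = tmp_path / "sheet.vtk"
        p.write_text(text)
        spec = {name: [i % 4] for i, name in enumerate(LANDMARK_NAMES)}
        mesh = vio.load_surface_mesh(p, spec)
        assert mesh.n_vertices == 4 and mesh.n_triangles == 2

    def test_vtu_export_is_valid_xml(self, la_surface, tmp_path):
        import xml.etree.ElementTree as ET

        out = vio.write_vtu(
            tmp_path / "field.vtu", la_surface,
            {"Vm": np.zeros(la_surface.n_vertices)},
        )
        root = ET.parse(out).getroot()
        assert root.tag == "VTKFile"
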