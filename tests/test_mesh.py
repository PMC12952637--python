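"""Mesh I/O, georeferencing and summary metrics."""

import numpy as np
import pytest

from boulderreef import (
    GeoreferenceError,
    KnownDistance,
    MeshError,
    ReferencePoint,
    SeafloorMesh,
    georeference,
    mesh_summary,
    read_mesh,
    write_mesh,
)
from boulderreef.mesh import read_reference_config
from boulderreef.synthetic import TerrainConfig, expected_vertex_count, generate_terrain

TET_V = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
TET_F = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def _tet():
    return SeafloorMesh(vertices=TET_V - [0, 0, 6], faces=TET_F)


class TestIO:
    @pytest.mark.parametrize("fmt", ["ply", "obj"])
    def test_round_trip_preserves_geometry(self, tmp_path, fmt):
        mesh = _tet()
        path = tmp_path / f"tet.{fmt}"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert back.n_vertices == 4 and back.n_faces == 4
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, mesh.faces)

    def test_double_round_trip_is_stable(self, tmp_path):
        mesh = _tet()
        p1, p2 = tmp_path / "a.ply", tmp_path / "b.ply"
        write_mesh(mesh, p1)
        write_mesh(read_mesh(p1), p2)
        np.testing.assert_array_equal(read_mesh(p1).vertices, read_mesh(p2).vertices)

    def test_point_cloud_round_trip(self, tmp_path):
        cloud = SeafloorMesh(vertices=TET_V, faces=np.empty((0, 3), int))
        path = tmp_path / "cloud.ply"
        write_mesh(cloud, path)
        back = read_mesh(path)
        assert back.n_faces == 0
        np.testing.assert_allclose(back.vertices, cloud.vertices, atol=1e-6)

    def test_large_mesh_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        v = rng.uniform(-10, 10, (10_000, 3)).astype(np.float32).astype(float)
        mesh = SeafloorMesh(vertices=v, faces=np.array([[0, 1, 2]]))
        write_mesh(mesh, tmp_path / "big.ply")
        back = read_mesh(tmp_path / "big.ply")
        # coordinates written at full precision: bit-equal at float32 level
        np.testing.assert_array_equal(
            back.vertices.astype(np.float32), v.astype(np.float32)
        )

    def test_synthetic_terrain_vertex_count_matches_generator(self):
        cfg = TerrainConfig(extent=(10.0, 6.0), mesh_spacing=0.5, n_boulders=0,
                            ridge_count=0, cobble_density=0.0, margin=1.0)
        mesh, _ = generate_terrain(cfg)
        assert mesh.n_vertices == expected_vertex_count(cfg)

    def test_errors_are_distinct(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.ply")
        bad = tmp_path / "bad.ply"
        bad.write_text("ply\nnot a real header\n")
        with pytest.raises(MeshError):
            read_mesh(bad)
        with pytest.raises(MeshError):
            SeafloorMesh(vertices=np.zeros((2, 3)), faces=np.empty((0, 3), int))
        with pytest.raises(MeshError):
            SeafloorMesh(vertices=TET_V, faces=np.array([[0, 1, 9]]))


def _square_refs(depths=(5.0, 5.0, 5.0, 5.0), side=10.0):
    pos = [(0, 0, -depths[0]), (side, 0, -depths[1]),
           (side, side, -depths[2]), (0, side, -depths[3])]
    return [ReferencePoint(f"R{i}", p, d) for i, (p, d) in enumerate(zip(pos, depths))]


class TestGeoreference:
    def test_already_georeferenced_is_near_identity(self):
        refs = _square_refs()
        mesh, _ = generate_terrain(TerrainConfig(
            extent=(10, 10), n_boulders=0, ridge_count=0, cobble_density=0.0,
            mesh_spacing=1.0, margin=1.0, depth_range=(4.9, 5.1), noise_amplitude=0.0))
        # canonicalise once, then re-apply with refs read off the result
        res1 = georeference(mesh, refs, KnownDistance("R0", "R1", 10.0))
        refs2 = [
            ReferencePoint(r.name, tuple(p), -p[2])
            for r, p in zip(refs, np.array([
                res1.scale * (np.array(r.model_position) @ res1.rotation.T) + res1.translation
                for r in refs]))
        ]
        d2 = np.linalg.norm(np.array(refs2[0].model_position) - np.array(refs2[1].model_position))
        res2 = georeference(res1.mesh, refs2, KnownDistance("R0", "R1", float(d2)))
        assert abs(res2.scale - 1) < 1e-9
        np.testing.assert_allclose(res2.mesh.vertices, res1.mesh.vertices, atol=1e-9)

    def test_known_distance_forces_scale(self):
        refs = _square_refs()
        mesh = SeafloorMesh(vertices=TET_V * 2 - [0, 0, 10], faces=TET_F)
        scaled_refs = [
            ReferencePoint(r.name, tuple(2 * np.array(r.model_position)), r.known_depth)
            for r in refs
        ]
        res = georeference(mesh, scaled_refs, KnownDistance("R0", "R1", 10.0))
        assert res.scale == pytest.approx(0.5, abs=1e-12)

    def test_self_inverse_recovers_vertices(self):
        """Canonical form is invariant: distorting the model by a random
        similarity and re-georeferencing lands on the same vertices."""
        rng = np.random.default_rng(3)
        mesh, _ = generate_terrain(TerrainConfig(
            extent=(12, 8), n_boulders=3, ridge_count=1, mesh_spacing=0.4,
            margin=2.0, seed=5))
        idx = [0, mesh.n_vertices // 2, mesh.n_vertices - 1, mesh.n_vertices // 3]
        refs = [
            ReferencePoint(f"R{i}", tuple(mesh.vertices[j]), -mesh.vertices[j, 2])
            for i, j in enumerate(idx)
        ]
        true_d = float(np.linalg.norm(mesh.vertices[idx[0]] - mesh.vertices[idx[1]]))
        res0 = georeference(mesh, refs, KnownDistance("R0", "R1", true_d))

        # random similarity distortion
        s = rng.uniform(0.5, 2.0)
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        t = rng.uniform(-50, 50, 3)
        distorted = mesh.with_vertices(s * (mesh.vertices @ Q.T) + t)
        refs_d = [
            ReferencePoint(r.name, tuple(s * (np.array(r.model_position) @ Q.T) + t),
                           r.known_depth)
            for r in refs
        ]
        res1 = georeference(distorted, refs_d, KnownDistance("R0", "R1", true_d))
        rms = np.sqrt(np.mean((res1.mesh.vertices - res0.mesh.vertices) ** 2))
        assert rms < 1e-6
        assert res1.depth_rms < 1e-6

    def test_idempotent(self):
        mesh, _ = generate_terrain(TerrainConfig(
            extent=(10, 10), n_boulders=0, ridge_count=0, mesh_spacing=1.0,
            margin=1.0, seed=1))
        idx = [0, 10, 120]
        refs = [ReferencePoint(f"R{i}", tuple(mesh.vertices[j]), -mesh.vertices[j, 2])
                for i, j in enumerate(idx)]
        res1 = georeference(mesh, refs)
        refs2 = [ReferencePoint(r.name,
                                tuple(res1.scale * (np.array(r.model_position) @ res1.rotation.T)
                                      + res1.translation),
                                r.known_depth) for r in refs]
        res2 = georeference(res1.mesh, refs2)
        assert np.abs(res2.mesh.vertices - res1.mesh.vertices).max() < 1e-9

    def test_collinear_refs_rejected(self):
        refs = [ReferencePoint(f"R{i}", (float(i), 0.0, -5.0), 5.0) for i in range(3)]
        with pytest.raises(GeoreferenceError, match="collinear"):
            georeference(_tet(), refs)

    def test_too_few_refs_rejected(self):
        with pytest.raises(GeoreferenceError, match="at least 3"):
            georeference(_tet(), _square_refs()[:2])

    def test_reference_config_round_trip(self, tmp_path):
        cfg = tmp_path / "refs.json"
        cfg.write_text(
            '{"references": ['
            '{"name": "A", "x": 0, "y": 0, "z": -5, "depth_m": 5.0},'
            '{"name": "B", "x": 10, "y": 0, "z": -5, "depth_m": 5.0},'
            '{"name": "C", "x": 0, "y": 10, "z": -6, "depth_m": 6.0}],'
            '"distance": {"ref_a": "A", "ref_b": "B", "meters": 10.0}}'
        )
        refs, dist = read_reference_config(cfg)
        assert len(refs) == 3 and refs[2].known_depth == 6.0
        assert dist.meters == 10.0


class TestMeshSummary:
    def test_unit_square_area(self):
        mesh = SeafloorMesh(
            vertices=np.array([[0, 0, -5], [1, 0, -5], [1, 1, -5], [0, 1, -5.0]]),
            faces=np.array([[0, 1, 2], [0, 2, 3]]),
        )
        s = mesh_summary(mesh)
        assert s.horizontal_area == pytest.approx(1.0)
        assert s.vertex_count == 4

    def test_regular_grid_resolution(self):
        xs = np.arange(0, 1.01, 0.1)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        v = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, -5.0)])
        mesh = SeafloorMesh(vertices=v, faces=np.array([[0, 1, len(xs)]]))
        assert mesh_summary(mesh).mean_vertex_resolution == pytest.approx(0.1)

    def test_resolution_matches_brute_force(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(0, 5, (120, 3))
        mesh = SeafloorMesh(vertices=v, faces=np.array([[0, 1, 2]]))
        # independent O(n^2) nearest-neighbour scan
        d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        expected = d.min(axis=1).mean()
        assert mesh_summary(mesh).mean_vertex_resolution == pytest.approx(expected, rel=1e-12)

    def test_area_invariant_under_yaw_and_translation(self):
        mesh, _ = generate_terrain(TerrainConfig(
            extent=(6, 6), n_boulders=0, ridge_count=0, mesh_spacing=0.5,
            margin=1.0, seed=2))
        a0 = mesh_summary(mesh).horizontal_area
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = mesh.with_vertices(mesh.vertices @ R.T + [100, -40, 0])
        assert mesh_summary(moved).horizontal_area == pytest.approx(a0, rel=1e-9)

    def test_degenerate_rejected(self):
        mesh = SeafloorMesh(vertices=np.zeros((4, 3)), faces=TET_F)
        with pytest.raises(MeshError):
            mesh_summary(mesh)
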