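import numpy as np
import pytest

from boulderreef import (
    IndicatorConfig,
    SeafloorMesh,
    TerrainConfig,
    boulder_indicators,
    generate_terrain,
    make_fixture,
)


@pytest.fixture(scope="session")
def tiny_scene():
    return make_fixture("tiny_scene", seed=7)


@pytest.fixture(scope="session")
def flat_plane():
    return make_fixture("flat_plane", seed=7)


@pytest.fixture(scope="session")
def single_boulder():
    return make_fixture("single_boulder", seed=7)


@pytest.fixture(scope="session")
def pile_scene():
    return make_fixture("pile", seed=7)


def rough_terrain(n_vertices: int, extent=(8.0, 8.0), relief=0.6, seed=0) -> SeafloorMesh:
    """Small random rough terrain for oracle-equivalence tests: jittered
    grid points with random relief, plus a trivial fan triangulation."""
    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(np.sqrt(n_vertices)))
    xs = np.linspace(0, extent[0], n_side)
    ys = np.linspace(0, extent[1], n_side)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])[:n_vertices]
    pts += rng.uniform(-0.3, 0.3, pts.shape) * (extent[0] / n_side)
    z = -6.0 + relief * rng.standard_normal(len(pts))
    faces = np.array([[0, i, i + 1] for i in range(1, min(len(pts) - 1, 10))])
    return SeafloorMesh(vertices=np.column_stack([pts, z]), faces=faces)


@pytest.fixture(scope="session")
def power_scene():
    """Moderate synthetic site with per-boulder indicators, shared by the
    planted-effect power checks (terrain + indicator pass computed once)."""
    cfg = TerrainConfig(
        extent=(40.0, 12.0), depth_range=(5.0, 8.0), ridge_count=3,
        ridge_width=3.5, cobble_density=1.5, n_boulders=160,
        pile_fraction=0.15, ridge_target_fraction=0.6,
        mesh_spacing=0.15, noise_amplitude=0.06, margin=2.5, seed=42,
    )
    mesh, annotations = generate_terrain(cfg)
    table = boulder_indicators(mesh, annotations, IndicatorConfig())
    return mesh, annotations, table
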