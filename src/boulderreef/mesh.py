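"""Seafloor mesh I/O, georeferencing and summary metrics.

The mesh is a triangulated seafloor surface in a metric, right-handed local
frame: x/y horizontal metres, z elevation in metres with the sea-surface
datum at z = 0, so depth = -z and the deepest point is the minimum z.

Georeferencing follows the field workflow for photogrammetric models: the
raw model comes out of structure-from-motion in an arbitrary similarity
frame, and is pinned to the world using a handful of reference points of
known depth plus (optionally) one tape-measured inter-point distance that
fixes the metric scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union


class MeshError(ValueError):
    """Raised for malformed, degenerate or unreadable mesh input."""


class GeoreferenceError(ValueError):
    """Raised when reference points cannot determine the transform."""


@dataclass(frozen=True)
class SeafloorMesh:
    """Triangulated seafloor surface.

    vertices : (n, 3) float array, x/y horizontal metres, z elevation
        (negative below the sea-surface datum).
    faces : (m, 3) int array of vertex-index triples; may be empty for a
        bare point cloud.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if v.shape[0] < 3:
            raise MeshError(f"mesh needs at least 3 vertices, got {v.shape[0]}")
        if not np.isfinite(v).all():
            raise MeshError("vertices contain non-finite coordinates")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def depths(self) -> np.ndarray:
        """Per-vertex depth below datum in metres (-z)."""
        return -self.vertices[:, 2]

    def with_vertices(self, vertices: np.ndarray) -> "SeafloorMesh":
        return SeafloorMesh(vertices=np.asarray(vertices, float), faces=self.faces)


@dataclass(frozen=True)
class ReferencePoint:
    """A surveyed point: its position in the raw model frame and the depth
    (metres below datum, positive) measured in the field."""

    name: str
    model_position: tuple[float, float, float]
    known_depth: float

    def __post_init__(self):
        if not self.known_depth > 0:
            raise GeoreferenceError(
                f"reference {self.name!r}: known_depth must be > 0 m"
            )


@dataclass(frozen=True)
class KnownDistance:
    """True distance in metres between two named reference points."""

    ref_a: str
    ref_b: str
    meters: float

    def __post_init__(self):
        if not self.meters > 0:
            raise GeoreferenceError("known distance must be positive")


@dataclass(frozen=True)
class GeoreferenceResult:
    mesh: SeafloorMesh
    scale: float
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    depth_residuals: np.ndarray  # per-reference, metres

    @property
    def depth_rms(self) -> float:
        return float(np.sqrt(np.mean(self.depth_residuals**2)))


@dataclass(frozen=True)
class MeshSummary:
    horizontal_area: float  # m^2, union of horizontally projected faces
    mean_vertex_resolution: float  # m, mean 3D nearest-neighbour spacing
    vertex_count: int


_FORMATS = ("ply", "obj")


def _infer_format(path: Path, format: str | None) -> str:
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path: str | Path, format: str | None = None) -> SeafloorMesh:
    """Read a PLY or OBJ mesh, preserving vertex order.

    The format is inferred from the file extension unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = _infer_format(path, format)
    try:
        loaded = trimesh.load(
            str(path), file_type=fmt, process=False, maintain_order=True
        )
    except Exception as exc:  # trimesh raises a zoo of types
        raise MeshError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if isinstance(loaded, trimesh.points.PointCloud):
        vertices = np.asarray(loaded.vertices, float)
        faces = np.empty((0, 3), dtype=np.int64)
    elif isinstance(loaded, trimesh.Trimesh):
        vertices = np.asarray(loaded.vertices, float)
        faces = np.asarray(loaded.faces, np.int64)
    else:
        raise MeshError(f"{path}: not a single triangulated mesh ({type(loaded).__name__})")
    if len(vertices) == 0:
        raise MeshError(f"{path}: mesh has zero vertices")
    return SeafloorMesh(vertices=vertices, faces=faces)


def write_mesh(mesh: SeafloorMesh, path: str | Path, format: str | None = None) -> Path:
    """Write a mesh as ascii PLY or OBJ (geometry only, no materials)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if mesh.n_faces == 0:
            if fmt == "obj":
                raise MeshError("OBJ output requires faces; use PLY for point clouds")
            cloud = trimesh.points.PointCloud(mesh.vertices)
            path.write_bytes(cloud.export(file_type="ply"))
            return path
        tm = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces, process=False, maintain_order=True
        )
        if fmt == "ply":
            # binary little-endian: float32-exact coordinates on round trip
            data = trimesh.exchange.ply.export_ply(tm, encoding="binary_little_endian")
            path.write_bytes(data)
        else:
            path.write_text(trimesh.exchange.obj.export_obj(tm, include_texture=False))
    except OSError as exc:
        raise MeshError(f"cannot write mesh to {path}: {exc}") from exc
    return path


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b by the smallest
    angle (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c > 1 - 1e-15:
        return np.eye(3)
    if c < -1 + 1e-12:
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    v = np.cross(a, b)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def georeference(
    mesh: SeafloorMesh,
    refs: list[ReferencePoint],
    known_distance: KnownDistance | None = None,
) -> GeoreferenceResult:
    """Fit a similarity transform (uniform scale, rotation, translation)
    pinning the model to reference depths.

    Constraints, in order:

    * scale -- fixed by ``known_distance`` if supplied, else assumed 1
      (the model is taken to be metric already); depth differences alone
      can never fix scale and are never used for it;
    * tilt and vertical offset -- closed-form least squares so that the
      transformed z of each reference equals minus its known depth;
    * yaw and horizontal offset -- not constrained by depths, so they are
      canonicalised: reference centroid at the xy origin, first reference
      on the +x half-axis.  This makes the operation deterministic and
      idempotent.

    Per-reference depth residuals are reported, never hidden.
    """
    if len(refs) < 3:
        raise GeoreferenceError(f"need at least 3 reference points, got {len(refs)}")
    P = np.array([r.model_position for r in refs], dtype=float)
    depths = np.array([r.known_depth for r in refs], dtype=float)

    # collinearity check (rank of the centred ref cloud)
    Pc = P - P.mean(axis=0)
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise GeoreferenceError("reference points are collinear; orientation is underdetermined")

    # --- scale ---
    if known_distance is not None:
        by_name = {r.name: r for r in refs}
        for nm in (known_distance.ref_a, known_distance.ref_b):
            if nm not in by_name:
                raise GeoreferenceError(f"known distance names unknown reference {nm!r}")
        d_model = np.linalg.norm(
            np.asarray(by_name[known_distance.ref_a].model_position)
            - np.asarray(by_name[known_distance.ref_b].model_position)
        )
        if d_model <= 0:
            raise GeoreferenceError("known-distance reference pair coincides in model space")
        scale = known_distance.meters / d_model
    else:
        scale = 1.0
    if not scale > 0:
        raise GeoreferenceError("non-positive scale")

    Q = scale * P
    z_target = -depths

    # --- tilt: find the model-frame "up" direction w = R^T e_z such that
    # w . q_i ~ z_target_i (least squares, |w| = 1). The centred normal
    # equations determine w's in-plane part; the out-of-plane part comes
    # from the unit-norm constraint, signed toward the model's up side.
    Qc = Q - Q.mean(axis=0)
    zc = z_target - z_target.mean()
    w_in, *_ = np.linalg.lstsq(Qc, zc, rcond=None)
    nrm = float(np.linalg.norm(w_in))
    if nrm > 1.0:
        # depth differences steeper than the model geometry allows
        if nrm > 1.0 + 1e-9:
            raise GeoreferenceError(
                "reference depths are inconsistent with reference geometry "
                f"(implied slope {nrm:.3f} > 1)"
            )
        w_in = w_in / nrm
    # plane normal of refs, oriented to +z of the model frame
    _, _, Vt = np.linalg.svd(Qc)
    n = Vt[2]
    if n[2] < 0:
        n = -n
    w = w_in + np.sqrt(max(0.0, 1.0 - float(w_in @ w_in))) * n
    w /= np.linalg.norm(w)
    R_tilt = _minimal_rotation(w, np.array([0.0, 0.0, 1.0]))

    Q2 = Q @ R_tilt.T
    # --- yaw canonicalisation: first ref on the +x half-axis from centroid
    c2 = Q2.mean(axis=0)
    dxy = Q2[0, :2] - c2[:2]
    if np.linalg.norm(dxy) > 1e-12:
        theta = -np.arctan2(dxy[1], dxy[0])
    else:
        theta = 0.0
    ct, st = np.cos(theta), np.sin(theta)
    R_yaw = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
    R = R_yaw @ R_tilt

    Q3 = Q @ R.T
    c3 = Q3.mean(axis=0)
    tz = float(np.mean(z_target - Q3[:, 2]))
    t = np.array([-c3[0], -c3[1], tz])

    new_refs_z = Q3[:, 2] + tz
    residuals = new_refs_z - z_target

    V = scale * (mesh.vertices @ R.T) + t
    return GeoreferenceResult(
        mesh=mesh.with_vertices(V),
        scale=float(scale),
        rotation=R,
        translation=t,
        depth_residuals=residuals,
    )


def transform_points(result: GeoreferenceResult, points: np.ndarray) -> np.ndarray:
    """Apply a fitted georeference transform to arbitrary model-frame points."""
    pts = np.atleast_2d(np.asarray(points, float))
    return result.scale * (pts @ result.rotation.T) + result.translation


def mesh_summary(mesh: SeafloorMesh) -> MeshSummary:
    """Horizontal footprint area, mean vertex spacing and vertex count.

    The footprint is the area of the union of the horizontally projected
    triangles (overlaps from overhangs counted once); vertex resolution is
    the mean 3D nearest-neighbour distance over all vertices.
    """
    V = mesh.vertices
    if len(V) < 2:
        raise MeshError("mesh summary needs at least 2 vertices")
    tree = cKDTree(V)
    dist, _ = tree.query(V, k=2)
    nn = dist[:, 1]
    if not (nn > 0).any():
        raise MeshError("degenerate mesh: all vertices coincident")
    resolution = float(nn.mean())

    if mesh.n_faces:
        tris = V[mesh.faces][:, :, :2]
        polys = [Polygon(t) for t in tris]
        polys = [p for p in polys if p.is_valid and p.area > 0]
        area = float(unary_union(polys).area) if polys else 0.0
    else:
        area = 0.0
    if not area > 0:
        raise MeshError("mesh has no horizontal footprint area (no non-degenerate faces)")
    return MeshSummary(
        horizontal_area=area,
        mean_vertex_resolution=resolution,
        vertex_count=mesh.n_vertices,
    )


def read_reference_config(path: str | Path) -> tuple[list[ReferencePoint], KnownDistance | None]:
    """Read reference points (and optional known distance) from a YAML/JSON-style
    structured text file.

    Expected keys::

        references:
          - {name: A, x: ..., y: ..., z: ..., depth_m: ...}
        distance: {ref_a: A, ref_b: B, meters: ...}   # optional
    """
    import json

    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml  # lazy: only needed for the YAML dialect

        data = yaml.safe_load(text)
    refs = [
        ReferencePoint(
            name=str(r["name"]),
            model_position=(float(r["x"]), float(r["y"]), float(r["z"])),
            known_depth=float(r["depth_m"]),
        )
        for r in data["references"]
    ]
    dist = None
    if data.get("distance"):
        d = data["distance"]
        dist = KnownDistance(str(d["ref_a"]), str(d["ref_b"]), float(d["meters"]))
    return refs, dist
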