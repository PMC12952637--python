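"""Georeference a raw model and render the vegetation map.

A photogrammetric model comes out of reconstruction in an arbitrary
similarity frame. Three reference points of known depth plus one taped
distance pin down scale, tilt and vertical datum; the fitted transform
and its per-reference depth residuals are reported. The classified
boulders are then emitted as a GeoJSON vegetation map.
"""

import numpy as np

from boulderreef import (
    KnownDistance,
    ReferencePoint,
    georeference,
    make_fixture,
    render_vegetation_map,
)

mesh, annotations, records = make_fixture("tiny_scene", seed=7)

# distort the mesh the way a raw reconstruction would be: wrong scale,
# arbitrary rotation, arbitrary origin
rng = np.random.default_rng(0)
Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
if np.linalg.det(Q) < 0:
    Q[:, 0] *= -1
raw = mesh.with_vertices(1.7 * (mesh.vertices @ Q.T) + [40.0, -3.0, 12.0])

idx = [0, mesh.n_vertices // 3, mesh.n_vertices - 1]
refs = [
    ReferencePoint(f"R{i}", tuple(raw.vertices[j]), -mesh.vertices[j, 2])
    for i, j in enumerate(idx)
]
tape = KnownDistance("R0", "R1", float(np.linalg.norm(mesh.vertices[idx[0]] - mesh.vertices[idx[1]])))

result = georeference(raw, refs, tape)
print(f"fitted scale:        {result.scale:.4f} (true distortion was 1.7)")
print(f"depth residual RMS:  {result.depth_rms:.2e} m")

geojson = render_vegetation_map(records, annotations)
print(f"vegetation map:      {len(geojson['features'])} boulder features")
print("first feature props:", geojson["features"][0]["properties"])
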