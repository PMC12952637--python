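"""Generate a synthetic boulder-reef site and summarise its mesh.

Builds a small sloping sandy seafloor crossed by a cobble ridge, seeds it
with 1 m boulders, and prints the mesh summary metrics a survey report
would quote.
"""

from boulderreef import TerrainConfig, generate_terrain, mesh_summary

config = TerrainConfig(
    extent=(30.0, 12.0),      # metres
    depth_range=(5.0, 8.0),   # shallow -> deep edge
    ridge_count=2,
    n_boulders=30,
    mesh_spacing=0.2,
    seed=7,
)
mesh, annotations = generate_terrain(config)
summary = mesh_summary(mesh)

n_sand = sum(a.bottom_type == "sand" for a in annotations)
print(f"vertices:            {summary.vertex_count}")
print(f"horizontal area:     {summary.horizontal_area:.1f} m^2")
print(f"vertex resolution:   {summary.mean_vertex_resolution * 100:.1f} cm")
print(f"boulders:            {len(annotations)} "
      f"({n_sand} on sand, {len(annotations) - n_sand} on cobble)")
# The area is the horizontally projected footprint of the mapped surface;
# resolution is the mean nearest-neighbour spacing between mesh vertices.
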