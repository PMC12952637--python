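# boulderreef

Analysis toolkit for **man-made boulder reefs** — natural-rock boulders (~1 m)
installed on the seafloor to seed macroalgal beds — mapped by underwater
photogrammetry. It is written for benthic-habitat and restoration ecologists
who have a triangulated seafloor mesh, a table of annotated boulders, and
per-boulder species presence/absence, and who want to know *where* rich
vegetation establishes and *which* terrain favours it.

The package covers the post-reconstruction half of such a survey:

1. **Mesh handling** — read/write PLY/OBJ seafloor meshes; georeference a raw
   photogrammetric model against ≥3 reference points of known depth (plus one
   taped inter-point distance for scale) by a fitted similarity transform;
   report footprint area and mean vertex resolution.
2. **Geomorphic indicators**, computed per vertex and read at each boulder's
   summit:
   - *relative height* `RH(v) = z(v) − min{ z(u) : ‖u − v‖ ≤ r }` with
     r = 1.5 m — elevation above the deepest point nearby;
   - *surface complexity* — box-counting occupancy: an L = 3.0 m cube around
     the vertex is cut into (L/ℓ)³ = 6³ = 216 cells of ℓ = 0.5 m, and
     `SC = (# cells containing ≥ 1 vertex) / 216`. Flat sand scores ≈ 36/216;
     piled boulders score higher.
   Vertices whose window leaves the mapped area are edge-excluded
   (`valid = False`), never silently dropped.
3. **Vegetation classification** — five scored taxa (*U. pinnatifida*,
   perennial *Sargassum* spp., *S. horneri*, *C. sinuosa*, geniculate
   coralline red algae) map through a priority cascade to seven community
   types with ordinal scores 0 (bare rock) … 6 (mixed perennial
   *Sargassum* + *U. pinnatifida* bed); scores ≥ 3 count as **rich**, ≤ 2 as
   **poor** vegetation.
4. **Statistics** — Welch's unequal-variance t-test (Welch–Satterthwaite df)
   and Pearson correlation with t-based two-sided p-values, assembled into a
   stratified report: prevalence and community tables, mean score per bottom
   type, score–indicator correlations overall and per stratum, and rich/poor
   indicator comparisons.
5. **Synthetic seafloor generator** — sloping sandy terrain crossed by rugose
   cobble ridges, spherical-cap boulders (isolated or piled), and
   bottom-type-calibrated Bernoulli species presence, so the whole pipeline is
   testable without field data.

## Worked example

```python
from boulderreef import (TerrainConfig, generate_terrain, boulder_indicators,
                         generate_presence, PresenceModel, run_full_analysis)

mesh, annotations = generate_terrain(TerrainConfig(
    extent=(40.0, 15.0), n_boulders=200, mesh_spacing=0.15, ridge_count=3, seed=11))
indicators = boulder_indicators(mesh, annotations)
records = generate_presence(annotations, PresenceModel(seed=12), indicators=indicators)
print(run_full_analysis(records).to_text())
```

prints (abridged):

```
records: 200 (sand 108, cobble 92)
...
Mean vegetation score: sand 3.6 (n=108), cobble 1.1 (n=92)
Welch's t (score ~ bottom type): t=12.002, df=170.1, p=1.95e-24
Score-indicator Pearson correlations (raw p):
  overall  relative_height    r=-0.234  p=0.000873  n=200
  overall  surface_complexity r=-0.185  p=0.00873  n=200
```

Boulders on sand carry far richer vegetation than boulders on cobble (mean
score 3.6 vs 1.1, decisively significant), and because cobble terrain is both
rougher and vegetation-poorer, the pooled score–indicator correlations come
out negative even though no indicator effect was planted — exactly the
confounding pattern that motivates the per-stratum correlations in the same
report. `examples/` contains this and four other narrative scripts
(simulation, indicators, classification, georeferencing + mapping).

A thin CLI wraps the same library:

```sh
boulderreef simulate --seed 3 --out site/
boulderreef indicators site/mesh.ply site/annotations.csv --out site/
boulderreef analyze site/presence.csv --indicators site/indicators.csv --out site/
boulderreef map site/classified.csv site/annotations.csv --out site/
```

Every run writes a manifest (inputs, config hash, seed, version) sufficient
to reproduce its outputs byte for byte.

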