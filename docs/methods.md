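# Methods

This note records what the package computes, the assumptions behind each
stage, and the choices made where the design was genuinely open.

## Coordinate convention

Meshes live in a metric local frame: x/y horizontal metres, z elevation with
the sea-surface datum at z = 0. Depth is −z, so "the deepest point" is the
minimum z — this keeps the relative-height formula free of sign ambiguity.

## Georeferencing

A photogrammetric reconstruction leaves the model in an arbitrary similarity
frame. `georeference` fits the 7-parameter similarity transform (uniform
scale s, rotation R, translation t) from ≥3 non-collinear reference points of
known depth, optionally with one taped inter-point distance:

- **Scale** comes only from the known distance (s = true/model distance).
  Without one, s = 1 is assumed — depth differences alone can never identify
  scale, so the package never tries to estimate it from them.
- **Tilt and vertical offset** are fitted in closed form: the model-frame
  "up" direction w = Rᵀe_z must satisfy w·(qᵢ − q̄) ≈ z*ᵢ − z̄* where
  qᵢ are the scaled reference positions and z*ᵢ = −depthᵢ. The centred
  linear least-squares solution gives w's component in the reference plane;
  the unit-norm constraint fixes the out-of-plane component (signed toward
  the model's upward side). The fit is exact for three consistent references;
  with more, it is least squares in the depth residuals, which are reported,
  never hidden. If the implied slope exceeds 1 the depths are geometrically
  inconsistent and the fit is refused. (For strongly non-coplanar reference
  sets the in-plane/normal split is approximate; survey references on a
  seafloor are effectively coplanar.)
- **Yaw and horizontal offset** are not constrained by depths at all. Rather
  than leave 3 degrees of freedom floating, the output is canonicalised:
  reference centroid at the xy origin, first reference on the +x half-axis.
  This makes georeferencing deterministic and idempotent, and means two
  differently-distorted copies of the same site land on identical
  coordinates.

Note the fitted transform makes the reference plane horizontal only when all
reference depths are equal; with unequal depths the depth fit takes
precedence (the true plane through such points is not horizontal).

## Mesh summary metrics

Footprint area is the area of the union of the horizontally projected
triangles (overhangs counted once, via polygon union); vertex resolution is
the mean 3D nearest-neighbour distance over vertices — the standard reading
of "vertex resolution" for an irregular mesh, and the one that is directly
testable against an exhaustive scan.

## Geomorphic indicators

- **Relative height** (default radius 1.5 m) uses a *3D* Euclidean radius
  query on the vertex cloud. A horizontal-disc query is the plausible
  alternative; at 1.5 m radius on ≤ 1 m relief the difference is negligible,
  and the choice is isolated inside one function should anyone want to swap
  it.
- **Surface complexity** (default 3.0 m window, 0.5 m cells, 6³ = 216 cells)
  counts cells occupied by *vertices*, not cells merely crossed by triangle
  faces. Cells are half-open [a, a + ℓ) anchored at the window's minimum
  corner, with the target vertex at the window centre — a deterministic
  tie-break for points exactly on cell boundaries. The centre vertex always
  occupies its own cell, so valid values lie in [1/216, 1]. A 2D mode
  (6² = 36 cells) exists for the planar worked example and didactic use.
- **Edge exclusion** invalidates any vertex whose full 3.0 m window square
  (horizontal projection) leaves the 2D convex hull of the projected
  vertices. Only the larger support is tested: a window that fits contains
  the 1.5 m disc. Convexity makes the test exact via the four window corners.
- **Per-boulder values** are read at the boulder's *summit* — the
  highest-elevation vertex inside the annotated circular footprint, ties
  broken to the lowest vertex index. Boulder annotation is an input
  (boulders are identified manually on the orthomosaic); no automatic
  segmentation is attempted.

## Vegetation classification

The scoresheet's wildcard rows are implemented as a priority cascade —
perennial *Sargassum* ∧ *U. pinnatifida* → 6; perennial → 5; *S. horneri* →
4; *U. pinnatifida* → 3; coralline → 2; *C. sinuosa* → 1; else 0 — which is
the unique total function consistent with every row. The rich/poor
dichotomy is ≥ 3 / ≤ 2: a literal "greater than 3 / less than 2" reading
would leave scores 2–3 unassigned, and downstream comparisons need an
exhaustive partition, so score 3 counts as rich and score 2 as poor.
Presence tokens accept ASCII `-`, Unicode minus `−` and en dash; output
always writes ASCII. Percentages are printed to 1 decimal, half-up.

## Statistics

Welch's unequal-variance t (Welch–Satterthwaite df) and Pearson's r with the
t-based p-value, both two-sided, both computed through scipy.stats behind
the module interface; the test suite checks them against independent
closed-form recomputation to 1e-10 and checks the Welch null rejection rate
at α = 0.05 over 2,000 seeded replicates. Scores are treated as numeric 0–6,
raw p-values are reported and labelled as such, and no multiple-testing
correction is applied (none is claimed). Degenerate inputs (constant
samples, undersized groups) raise explicit errors; two constant but unequal
samples are reported as infinitely separated (p = 0) rather than an error.

## Synthetic generator

The generator emulates the target study system: an 80 m × 20 m seafloor
sloping from 4.5 m to 9.2 m depth, crossed by cobble ridges (Gaussian-bump
ridges of 0.5 m relief dressed with 0.2–0.5 m cobble caps), seeded with
1,111 boulders of 1 m diameter at 0.08 m mesh spacing — those are the
defaults; tests and examples use scaled-down scenes (10²–10³ boulder sites,
0.15–0.4 m spacing) chosen to exercise every code path at interactive cost.
Boulders are spherical caps (height = half the diameter by default);
piles are 2–4 overlapping caps with raised centres, which suffices to make
piles read higher on both indicators. Bottom type is read off the ridge
mask at the boulder's base; about half the placements target ridges so both
strata are populated.

Species presence is Bernoulli per species per boulder with bottom-type
probabilities (defaults: sand 0.793/0.584/0.396/0.264/0.056 and cobble
0.797/0.057/0.045/0.011/0.002 for *C. sinuosa* / *U. pinnatifida* /
perennial / coralline / *S. horneri*). The base model is covariate-free —
that is all a prevalence table identifies. Indicator effects are opt-in
logit slopes; the power check plants +5 logit units per metre of relative
height on perennial *Sargassum*, an effect size chosen once to be clearly
detectable at ~10² boulders without being degenerate, and requires recovery
(positive cobble-stratum correlation, p < 0.05) in ≥ 80% of 50 replicates.

One integer seed drives everything through spawned sub-streams (terrain
noise, ridge dressing, placement, presence), so identical configs give
byte-identical outputs and adding boulders does not reshuffle the terrain.

**What the generator does not emulate:** real boulder shapes (scanned rock,
not caps), photogrammetric noise and holes in the mesh, spatial
autocorrelation of species occurrence beyond the bottom-type contrast, and
any temporal dynamics (recruitment, grazing, succession). Passing tests
therefore demonstrate correctness of the *computations* under controlled
geometry and sampling — not ecological validity of any field inference.

## Numerical notes

- Radius queries use a k-d tree; the suite proves exact agreement with
  O(n²) scans on meshes up to 2,000 vertices.
- Box-count cell indices are floored after a half-open range test; an index
  exactly at the upper window edge is excluded, and a guard clip absorbs
  float round-off at the last cell boundary.
- PLY output is binary little-endian (float32-exact round trip); OBJ is
  ascii v/f records without materials. Point clouds (0 faces) are PLY-only.
- Mean scores are reported at full precision alongside the half-up 1-decimal
  rounding used for display.

## Known limitations

- Edge exclusion uses the convex hull; a concave mapped area (L-shaped
  survey) would validate vertices in the concavity that a true footprint
  test would reject.
- The georeference similarity fit assumes roughly coplanar references.
- `boulder_indicators` loops per boulder; for ≫10⁴ boulders a vectorised
  summit pass would be worth adding.
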