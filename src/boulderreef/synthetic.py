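"""Synthetic boulder-reef scenes for testing and calibration.

The generator emulates the kind of site the analysis targets: a gently
sloping sandy seafloor (default 80 m x 20 m, 4.5-9.2 m deep) crossed by
rugose cobble ridges, seeded with ~1 m artificial boulders placed either
isolated or in piles. Species presence on each boulder is drawn from
bottom-type-specific Bernoulli prevalences (defaults calibrated to the
observed sand/cobble prevalence contrast), optionally tilted on the logit
scale by the geomorphic indicators so that planted indicator effects can
be recovered by the analysis.

Everything is deterministic given the integer seed: one seed spawns
independent sub-streams per stage, so adding boulders does not reshuffle
the terrain noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geomorph import BoulderAnnotation, GeomorphicIndicators
from .mesh import SeafloorMesh
from .vegetation import SPECIES, SpeciesPresence, VegetationRecord


@dataclass(frozen=True)
class TerrainConfig:
    """Geometry of a synthetic site.

    Lengths in metres. ``extent`` is (length, width); the seafloor slopes
    from ``depth_range[0]`` at x=0 to ``depth_range[1]`` at x=length.
    ``pile_fraction`` of the boulders are placed in stacked clusters of
    2-4 caps. ``ridge_target_fraction`` is the share of boulders whose
    placement targets a ridge (ending up on cobble bottom).
    """

    extent: tuple[float, float] = (80.0, 20.0)
    depth_range: tuple[float, float] = (4.5, 9.2)
    ridge_count: int = 4
    ridge_width: float = 4.0
    ridge_relief: float = 0.5
    cobble_size_range: tuple[float, float] = (0.2, 0.5)
    cobble_density: float = 1.5  # cobbles per m^2 of ridge footprint
    boulder_diameter: float = 1.0
    boulder_height_ratio: float = 0.5  # cap height / diameter
    n_boulders: int = 1111
    pile_fraction: float = 0.1
    ridge_target_fraction: float = 0.5
    mesh_spacing: float = 0.08
    noise_amplitude: float = 0.08
    noise_scale: float = 4.0
    margin: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if not self.depth_range[1] > self.depth_range[0]:
            raise ValueError("depth_range must be (shallow, deep) with deep > shallow")
        if not self.mesh_spacing > 0:
            raise ValueError("mesh_spacing must be positive")
        if not 0.0 <= self.pile_fraction <= 1.0:
            raise ValueError("pile_fraction must be in [0, 1]")


#: Default per-species Bernoulli prevalences by bottom type, reflecting the
#: strong sand/cobble contrast of the calibration survey: the ephemeral
#: C. sinuosa is ubiquitous on both substrates while canopy formers are
#: largely confined to sand.
DEFAULT_PREVALENCE = {
    "sand": {
        "u_pinnatifida": 0.584,
        "perennial_sargassum": 0.396,
        "s_horneri": 0.056,
        "c_sinuosa": 0.793,
        "coralline": 0.264,
    },
    "cobble": {
        "u_pinnatifida": 0.057,
        "perennial_sargassum": 0.045,
        "s_horneri": 0.002,
        "c_sinuosa": 0.797,
        "coralline": 0.011,
    },
}


@dataclass(frozen=True)
class PresenceModel:
    """Bernoulli presence model.

    ``prevalence[bottom_type][species]`` is the base probability;
    ``logit_effects[species]`` is an optional (per-metre-relative-height,
    per-unit-surface-complexity) slope pair applied on the logit scale
    when indicators are available. Effects default to none: the base model
    is bottom-type-only, which is all the calibration data identifies.
    """

    prevalence: dict = field(default_factory=lambda: {
        bt: dict(sp) for bt, sp in DEFAULT_PREVALENCE.items()
    })
    logit_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for bt, probs in self.prevalence.items():
            for sp, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence[{bt}][{sp}] = {p} outside [0, 1]")


def _grid(config: TerrainConfig):
    L, W = config.extent
    nx = int(round(L / config.mesh_spacing)) + 1
    ny = int(round(W / config.mesh_spacing)) + 1
    x = np.linspace(0.0, L, nx)
    y = np.linspace(0.0, W, ny)
    return x, y


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    """Triangulate an nx-by-ny vertex grid (row-major, y fastest)."""
    i = np.arange(nx - 1)[:, None]
    j = np.arange(ny - 1)[None, :]
    v00 = (i * ny + j).ravel()
    v01 = v00 + 1
    v10 = v00 + ny
    v11 = v10 + 1
    return np.concatenate(
        [np.stack([v00, v10, v11], axis=1), np.stack([v00, v11, v01], axis=1)]
    ).astype(np.int64)


def _cap_height(r2: np.ndarray, a: float, h: float) -> np.ndarray:
    """Height profile of a spherical cap with base radius a and height h,
    as a function of squared horizontal distance from the axis."""
    R = (a * a + h * h) / (2.0 * h)  # sphere radius
    out = np.sqrt(np.maximum(R * R - r2, 0.0)) - (R - h)
    return np.maximum(out, 0.0)


def _stamp_cap(Z, x, y, cx, cy, base, a, h):
    """Raise the height field to the cap surface (in place)."""
    i0, i1 = np.searchsorted(x, [cx - a, cx + a])
    j0, j1 = np.searchsorted(y, [cy - a, cy + a])
    i1 = min(i1 + 1, len(x))
    j1 = min(j1 + 1, len(y))
    if i0 >= i1 or j0 >= j1:
        return
    xs = x[i0:i1][:, None]
    ys = y[j0:j1][None, :]
    r2 = (xs - cx) ** 2 + (ys - cy) ** 2
    cap = np.where(r2 <= a * a, base + _cap_height(r2, a, h), -np.inf)
    Z[i0:i1, j0:j1] = np.maximum(Z[i0:i1, j0:j1], cap)


def _base_height(config: TerrainConfig, x, y, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sloping sand + smooth noise + ridge bumps. Returns (Z, ridge_centers)."""
    L, W = config.extent
    shallow, deep = config.depth_range
    Z = -(shallow + (deep - shallow) * (x[:, None] / L)) * np.ones((len(x), len(y)))
    if config.noise_amplitude > 0:
        white = rng.standard_normal((len(x), len(y)))
        sigma = max(config.noise_scale / config.mesh_spacing, 1.0)
        smooth = gaussian_filter(white, sigma=sigma, mode="nearest")
        sd = smooth.std()
        if sd > 0:
            Z += config.noise_amplitude * smooth / sd
    if config.ridge_count > 0:
        lo = config.margin + config.ridge_width
        hi = L - config.margin - config.ridge_width
        if hi <= lo:  # short site: allow ridges anywhere inside the margin
            lo, hi = config.margin, L - config.margin
        centers = np.sort(rng.uniform(lo, hi, size=config.ridge_count))
    else:
        centers = np.array([])
    for xc in centers:
        Z += config.ridge_relief * np.exp(
            -(((x[:, None] - xc) / (config.ridge_width / 2.0)) ** 2)
        )
    return Z, centers


def _on_ridge(xpos, centers, half_width):
    if len(centers) == 0:
        return np.zeros(np.shape(xpos), dtype=bool)
    d = np.abs(np.asarray(xpos)[..., None] - centers)
    return (d < half_width).any(axis=-1)


def generate_terrain(config: TerrainConfig) -> tuple[SeafloorMesh, list[BoulderAnnotation]]:
    """Build the synthetic site: height-field mesh plus one annotation per
    installed boulder (bottom type read off the ridge mask at its base)."""
    ss = np.random.SeedSequence(config.seed)
    rng_noise, rng_ridge, rng_place = [np.random.default_rng(s) for s in ss.spawn(3)]

    x, y = _grid(config)
    L, W = config.extent
    Z, ridge_centers = _base_height(config, x, y, rng_noise)
    half_w = config.ridge_width / 2.0

    def terrain_at(px, py):
        i = np.clip(np.searchsorted(x, px) - 1, 0, len(x) - 2)
        j = np.clip(np.searchsorted(y, py) - 1, 0, len(y) - 2)
        return Z[i, j]  # nearest-node is plenty for cap bases

    # cobbles scattered over the ridges make them rugose
    if len(ridge_centers) and config.cobble_density > 0:
        area = config.ridge_width * (W - 2 * config.margin)
        n_cob = rng_ridge.poisson(config.cobble_density * area * len(ridge_centers))
        for _ in range(int(n_cob)):
            xc = rng_ridge.choice(ridge_centers) + rng_ridge.uniform(-half_w, half_w)
            yc = rng_ridge.uniform(config.margin, W - config.margin)
            d = rng_ridge.uniform(*config.cobble_size_range)
            a = d / 2.0
            _stamp_cap(Z, x, y, xc, yc, terrain_at(xc, yc), a, a)

    # boulder placement: isolated boulders and stacked piles
    a_b = config.boulder_diameter / 2.0
    h_b = config.boulder_height_ratio * config.boulder_diameter
    lo_x, hi_x = config.margin, L - config.margin
    lo_y, hi_y = config.margin, W - config.margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("extent too small for the requested margin")

    placeable = (hi_x - lo_x) * (hi_y - lo_y)
    if config.n_boulders * np.pi * a_b**2 > 0.9 * placeable:
        raise ValueError(
            f"{config.n_boulders} boulders exceed the placeable area ({placeable:.0f} m^2)"
        )

    def sample_center(on_ridge_target: bool):
        for _ in range(200):
            if on_ridge_target and len(ridge_centers):
                xc = rng_place.choice(ridge_centers) + rng_place.uniform(-half_w, half_w)
                xc = float(np.clip(xc, lo_x, hi_x))
            else:
                xc = rng_place.uniform(lo_x, hi_x)
                if len(ridge_centers) and _on_ridge(xc, ridge_centers, half_w):
                    continue
            yc = rng_place.uniform(lo_y, hi_y)
            return xc, yc
        return rng_place.uniform(lo_x, hi_x), rng_place.uniform(lo_y, hi_y)

    n_pile_boulders = int(round(config.pile_fraction * config.n_boulders))
    annotations: list[BoulderAnnotation] = []
    bid = 0

    def add_boulder(cx, cy, lift):
        nonlocal bid
        base = terrain_at(cx, cy) + lift
        _stamp_cap(Z, x, y, cx, cy, base, a_b, h_b)
        bt = "cobble" if bool(_on_ridge(cx, ridge_centers, half_w)) else "sand"
        annotations.append(
            BoulderAnnotation(
                boulder_id=f"B{bid:04d}",
                center=(float(cx), float(cy)),
                footprint_radius=float(a_b),
                bottom_type=bt,
            )
        )
        bid += 1

    placed_piled = 0
    while placed_piled < n_pile_boulders:
        k = int(rng_place.integers(2, 5))
        k = min(k, n_pile_boulders - placed_piled + 1)
        if k < 2:
            k = 2
        cx, cy = sample_center(rng_place.random() < config.ridge_target_fraction)
        add_boulder(cx, cy, 0.0)
        for j in range(1, k):
            ang = rng_place.uniform(0, 2 * np.pi)
            off = rng_place.uniform(0.4, 0.8) * a_b
            lift = rng_place.uniform(0.3, 0.6) * h_b  # stacked, centre raised
            add_boulder(cx + off * np.cos(ang), cy + off * np.sin(ang), lift)
        placed_piled += k

    while bid < config.n_boulders:
        cx, cy = sample_center(rng_place.random() < config.ridge_target_fraction)
        add_boulder(cx, cy, 0.0)

    annotations = annotations[: config.n_boulders]

    nx, ny = len(x), len(y)
    V = np.column_stack(
        [np.repeat(x, ny), np.tile(y, nx), Z.ravel()]
    )
    mesh = SeafloorMesh(vertices=V, faces=_grid_faces(nx, ny))
    return mesh, annotations


def expected_vertex_count(config: TerrainConfig) -> int:
    x, y = _grid(config)
    return len(x) * len(y)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    return np.log(p / (1.0 - p))


def generate_presence(
    boulders: list[BoulderAnnotation],
    model: PresenceModel = PresenceModel(),
    indicators: pd.DataFrame | None = None,
) -> list[VegetationRecord]:
    """Draw species presence per boulder and return classified records.

    ``indicators`` is an optional per-boulder table (as produced by
    ``boulder_indicators``) joined on boulder_id; when supplied, its valid
    rows are attached to the records and any logit effects in the model
    act through them. Base probabilities apply where indicators are
    absent or invalid.
    """
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    ind_map = {}
    if indicators is not None:
        for r in indicators.itertuples():
            if r.valid:
                ind_map[str(r.boulder_id)] = GeomorphicIndicators(
                    relative_height=float(r.relative_height_m),
                    surface_complexity=float(r.surface_complexity),
                    valid=True,
                )
    records = []
    for b in boulders:
        probs = model.prevalence[b.bottom_type]
        ind = ind_map.get(b.boulder_id)
        flags = {}
        for sp in SPECIES:
            p = probs[sp]
            eff = model.logit_effects.get(sp)
            if eff is not None and ind is not None and 0.0 < p < 1.0:
                beta_rh, beta_sc = eff
                p = float(_sigmoid(_logit(p) + beta_rh * ind.relative_height
                                   + beta_sc * ind.surface_complexity))
            flags[sp] = bool(rng.random() < p)
        rec = VegetationRecord(
            boulder_id=b.boulder_id,
            presence=SpeciesPresence(**flags),
            bottom_type=b.bottom_type,
            indicators=ind,
        ).classify()
        records.append(rec)
    return records


FIXTURES = ("flat_plane", "single_boulder", "pile", "ridge_valley", "tiny_scene")


def make_fixture(name: str, seed: int = 0):
    """Small deterministic scenes (<= 5,000 vertices) used across the test
    suite: (mesh, annotations, records).

    * ``flat_plane`` -- featureless flat sand, no boulders;
    * ``single_boulder`` -- one isolated 1 m boulder on flat sand;
    * ``pile`` -- a stacked cluster of three caps on flat sand;
    * ``ridge_valley`` -- sand boulders in a valley enclosed by two cobble
      ridges carrying their own boulders;
    * ``tiny_scene`` -- a miniature end-to-end site with mixed placement.
    """
    flat = dict(
        extent=(14.0, 14.0), depth_range=(6.0, 6.000001), ridge_count=0,
        cobble_density=0.0, noise_amplitude=0.0, n_boulders=0,
        mesh_spacing=0.25, margin=2.5, seed=seed,
    )
    if name == "flat_plane":
        cfg = TerrainConfig(**flat)
    elif name == "single_boulder":
        cfg = TerrainConfig(**{**flat, "n_boulders": 1, "pile_fraction": 0.0})
    elif name == "pile":
        cfg = TerrainConfig(**{**flat, "n_boulders": 3, "pile_fraction": 1.0})
    elif name == "ridge_valley":
        cfg = TerrainConfig(
            extent=(26.0, 10.0), depth_range=(5.0, 6.0), ridge_count=2,
            ridge_width=3.0, ridge_relief=0.5, cobble_density=1.0,
            n_boulders=14, pile_fraction=0.0, ridge_target_fraction=0.5,
            mesh_spacing=0.25, noise_amplitude=0.03, margin=2.0, seed=seed,
        )
    elif name == "tiny_scene":
        cfg = TerrainConfig(
            extent=(20.0, 10.0), depth_range=(4.5, 6.5), ridge_count=1,
            ridge_width=3.0, cobble_density=1.0, n_boulders=12,
            pile_fraction=0.25, mesh_spacing=0.25, noise_amplitude=0.05,
            margin=2.0, seed=seed,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURES}")
    mesh, annotations = generate_terrain(cfg)
    records = generate_presence(annotations, PresenceModel(seed=seed + 1))
    return mesh, annotations, records
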