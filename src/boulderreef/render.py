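"""Vegetation-map output: one GeoJSON feature per boulder.

Each boulder becomes a circle polygon (its annotated footprint) carrying
community, score and bottom type, suitable for styling into the usual
colour-coded vegetation map. Feature order follows the annotation order,
so output is deterministic.
"""

from __future__ import annotations

import json

from shapely.geometry import Point, mapping

from .geomorph import BoulderAnnotation
from .vegetation import COMMUNITY_DISPLAY, VegetationRecord

_CIRCLE_SEGMENTS = 32


def render_vegetation_map(
    records: list[VegetationRecord],
    annotations: list[BoulderAnnotation],
) -> dict:
    """Join classified records to annotations on boulder_id and emit a
    GeoJSON FeatureCollection. Records without a matching annotation are
    an error (they cannot be drawn anywhere)."""
    ann_by_id = {a.boulder_id: a for a in annotations}
    missing = [r.boulder_id for r in records if r.boulder_id not in ann_by_id]
    if missing:
        raise ValueError(
            f"{len(missing)} record(s) have no matching annotation: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    rec_by_id = {r.boulder_id: r for r in records}
    features = []
    for ann in annotations:
        rec = rec_by_id.get(ann.boulder_id)
        if rec is None:
            continue
        circle = Point(ann.center).buffer(ann.footprint_radius, quad_segs=_CIRCLE_SEGMENTS // 4)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(circle),
                "properties": {
                    "boulder_id": ann.boulder_id,
                    "community": rec.community,
                    "community_label": COMMUNITY_DISPLAY[rec.community],
                    "score": rec.score,
                    "bottom_type": rec.bottom_type,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_vegetation_map(records, annotations, path) -> None:
    with open(path, "w") as fh:
        json.dump(render_vegetation_map(records, annotations), fh)


def render_map_image(records, annotations, path, dpi: int = 120) -> None:
    """Optional raster rendering of the same map (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("viridis", 7)
    rec_by_id = {r.boulder_id: r for r in records}
    fig, ax = plt.subplots(figsize=(10, 4))
    for ann in annotations:
        rec = rec_by_id.get(ann.boulder_id)
        if rec is None:
            continue
        ax.add_patch(
            plt.Circle(ann.center, ann.footprint_radius, color=cmap(rec.score))
        )
    xs = [a.center[0] for a in annotations] or [0]
    ys = [a.center[1] for a in annotations] or [0]
    ax.set_xlim(min(xs) - 2, max(xs) + 2)
    ax.set_ylim(min(ys) - 2, max(ys) + 2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title("Vegetation score per boulder")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
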