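"""Crop-index exposure assessment.

The Global Crop Index (GCI) of a residence is the percentage of
cultivated land inside a circular buffer (default radius 1 km) around
it, split into six crop subcategories (Irrigated, Rice, Vineyards,
Fruits, Olives, Heterogeneous).  Values are percentage points in
[0, 100]; the model covariate is GCI/10, so a unit coefficient
exponentiates to the odds ratio per 10-percentage-point increase.

The buffer circle is a 64-segment polygon and the denominator is the
area of that polygon, so full containment yields exactly 100.  Area
outside the landscape extent counts as non-crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .config import CROP_CATEGORIES
from .geoio import Landscape

logger = logging.getLogger(__name__)

#: quarter-circle segments of the buffer polygon (64 segments total,
#: area error ~1.6e-3 relative — below the 0.5-point test tolerance)
BUFFER_QUAD_SEGS = 16

__all__ = ["CropIndexSet", "crop_index", "crop_indices", "crop_index_oracle", "scale_for_model"]


@dataclass
class CropIndexSet:
    """Crop percentages inside one residence buffer."""

    gci: float
    by_category: dict[str, float] = field(default_factory=dict)
    radius_m: float = 1000.0

    def __post_init__(self):
        for cat in CROP_CATEGORIES:
            self.by_category.setdefault(cat, 0.0)


def _as_layer(land_cover) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(land_cover, Landscape):
        return land_cover.crop_polygons()
    polys, cats = land_cover
    polys = np.asarray(polys, dtype=object)
    cats = np.asarray(cats, dtype=object)
    mask = cats != "NonCrop"
    return polys[mask], cats[mask]


def _as_point(point):
    if isinstance(point, shapely.Geometry):
        return point
    x, y = point
    return shapely.points(x, y)


def crop_index(point, radius_m: float, land_cover) -> CropIndexSet:
    """Exact crop index of one residence.

    ``land_cover`` is a :class:`Landscape` or a ``(polygons,
    categories)`` pair.  Polygons sharing a category are unioned before
    intersection, so malformed overlapping inputs are not double
    counted.
    """
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    polys, cats = _as_layer(land_cover)
    if len(polys) == 0:
        logger.warning("empty land-cover layer: returning all-zero crop index")
        return CropIndexSet(gci=0.0, radius_m=radius_m)
    buffer = shapely.buffer(_as_point(point), radius_m, quad_segs=BUFFER_QUAD_SEGS)
    buf_area = shapely.area(buffer)
    tree = shapely.STRtree(polys)
    cand = tree.query(buffer, predicate="intersects")
    by_cat: dict[str, float] = {}
    for cat in CROP_CATEGORIES:
        sel = cand[cats[cand] == cat]
        if len(sel) == 0:
            by_cat[cat] = 0.0
            continue
        merged = shapely.unary_union(polys[sel])
        frac = 100.0 * shapely.area(shapely.intersection(buffer, merged)) / buf_area
        by_cat[cat] = float(np.clip(frac, 0.0, 100.0))
    return CropIndexSet(
        gci=float(np.clip(sum(by_cat.values()), 0.0, 100.0)),
        by_category=by_cat,
        radius_m=radius_m,
    )


def crop_indices(points, radius_m: float, land_cover) -> pd.DataFrame:
    """Vectorised exact crop indices for many residences.

    Assumes category polygons are pairwise disjoint (the layer partition
    invariant), so per-cell intersection areas can simply be summed.
    Returns a DataFrame with a ``gci`` column and one lower-cased column
    per crop subcategory, in percentage points.
    """
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    pts = np.asarray(points, dtype=object) if not isinstance(points, np.ndarray) else points
    polys, cats = _as_layer(land_cover)
    n = len(pts)
    out = np.zeros((n, len(CROP_CATEGORIES)))
    buffers = shapely.buffer(pts, radius_m, quad_segs=BUFFER_QUAD_SEGS)
    buf_area = shapely.area(buffers)
    if len(polys):
        cat_code = {c: k for k, c in enumerate(CROP_CATEGORIES)}
        codes = np.array([cat_code[c] for c in cats])
        tree = shapely.STRtree(polys)
        bi, ci = tree.query(buffers, predicate="intersects")
        if len(bi):
            areas = shapely.area(shapely.intersection(buffers[bi], polys[ci]))
            np.add.at(out, (bi, codes[ci]), areas)
        # clamp floating-point residue to the [0, 100] invariant
        out = np.clip(100.0 * out / buf_area[:, None], 0.0, 100.0)
    else:
        logger.warning("empty land-cover layer: returning all-zero crop indices")
    df = pd.DataFrame(out, columns=[c.lower() for c in CROP_CATEGORIES])
    df.insert(0, "gci", np.clip(out.sum(axis=1), 0.0, 100.0))
    return df


def crop_index_oracle(
    point, radius_m: float, land_cover, n_samples: int = 100_000, seed: int = 0
) -> CropIndexSet:
    """Brute-force Monte-Carlo crop index.

    Estimates each category fraction by uniform sampling inside the true
    disc and point-in-polygon counting.  Standard error is at most 0.5
    percentage points at the default 10^5 samples.  Independent of
    :func:`crop_index`; used to verify it.
    """
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    if n_samples < 10_000:
        raise ValueError("need at least 10^4 samples")
    polys, cats = _as_layer(land_cover)
    p = _as_point(point)
    cx, cy = shapely.get_x(p), shapely.get_y(p)
    rng = np.random.default_rng(seed)
    r = radius_m * np.sqrt(rng.random(n_samples))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_samples)
    xs, ys = cx + r * np.cos(theta), cy + r * np.sin(theta)
    by_cat = {c: 0.0 for c in CROP_CATEGORIES}
    any_crop = np.zeros(n_samples, dtype=bool)
    if len(polys):
        sample_pts = shapely.points(xs, ys)
        tree = shapely.STRtree(polys)
        pi, li = tree.query(sample_pts, predicate="intersects")
        for cat in CROP_CATEGORIES:
            hits = np.unique(pi[cats[li] == cat])
            by_cat[cat] = 100.0 * len(hits) / n_samples
            any_crop[hits] = True
    return CropIndexSet(
        gci=100.0 * any_crop.mean(), by_category=by_cat, radius_m=radius_m
    )


def scale_for_model(index: CropIndexSet | float) -> float:
    """The model covariate: GCI / 10 (odds ratio per 10-point increase)."""
    gci = index.gci if isinstance(index, CropIndexSet) else float(index)
    return gci / 10.0
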