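"""Synthetic landscapes, populations and outcomes.

This module emulates the data a registry-based spatial case-control
study consumes: a land-cover tessellation with six crop subcategories, an
industrial facility point process, towns of varying size, census tracts
carrying a socioeconomic value, a birth-registry pool of residences, and
case labels drawn from a logistic outcome model with configurable true
odds ratios.  Everything is a pure function of (config, seed).

Land cover and tracts are Voronoi tessellations of seeded uniform point
sets, mirrored across the extent edges so the cells partition the
rectangle exactly.  Tests must not depend on cell shapes — any partition
satisfying the layer invariants is equivalent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from scipy.special import expit
from shapely.geometry import Polygon

from . import published
from .config import (
    ConfigurationError,
    LandscapeConfig,
    PopulationConfig,
    StudyConfig,
    TrueParams,
)
from .geoio import Landscape

__all__ = [
    "generate_landscape",
    "generate_population",
    "assign_outcomes",
    "linear_predictor",
    "voronoi_partition",
]


# ---------------------------------------------------------------------------
# geometry helpers

def voronoi_partition(points: np.ndarray, extent) -> np.ndarray:
    """Voronoi cells of ``points`` clipped exactly to a rectangle.

    Points are mirrored across the four extent edges before triangulation,
    which bounds every original cell and makes the cells tile the
    rectangle without residue.
    """
    points = np.asarray(points, dtype=float)
    x0, y0, x1, y1 = extent
    mirrors = [
        np.column_stack([2 * x0 - points[:, 0], points[:, 1]]),
        np.column_stack([2 * x1 - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * y0 - points[:, 1]]),
        np.column_stack([points[:, 0], 2 * y1 - points[:, 1]]),
    ]
    vor = Voronoi(np.vstack([points] + mirrors))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # cells are convex; order vertices by angle around their mean
        center = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0]))
        cells.append(Polygon(verts[order]))
    return np.array(cells, dtype=object)


def _sample_in_polygon(rng: np.random.Generator, poly, n: int) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    x0, y0, x1, y1 = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        cand = np.column_stack(
            [rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)]
        )
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    return out[:n]


# ---------------------------------------------------------------------------
# landscape

def generate_landscape(config: StudyConfig | LandscapeConfig, seed: int) -> Landscape:
    """Generate the four spatial layers of one synthetic territory."""
    lc_cfg = config.landscape if isinstance(config, StudyConfig) else config
    lc_cfg.validate()
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = lc_cfg.extent
    extent_poly = shapely.box(*lc_cfg.extent)

    def uniform_points(n):
        return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])

    # land cover
    cells = voronoi_partition(uniform_points(lc_cfg.n_land_cells), lc_cfg.extent)
    cat_names = list(lc_cfg.category_weights)
    cat_p = np.array([lc_cfg.category_weights[c] for c in cat_names], dtype=float)
    cat_p = cat_p / cat_p.sum()
    categories = rng.choice(cat_names, size=len(cells), p=cat_p).astype(object)

    # census tracts
    tracts = voronoi_partition(uniform_points(lc_cfg.n_tracts), lc_cfg.extent)
    lo, hi = lc_cfg.ses_range
    ses = rng.uniform(lo, hi, len(tracts))

    # towns: discs of varying radius, population proportional to area
    centers = uniform_points(lc_cfg.n_urban)
    radii = rng.uniform(*lc_cfg.urban_radius_range, lc_cfg.n_urban)
    density = lc_cfg.urban_density_per_km2 * rng.lognormal(0.0, 0.3, lc_cfg.n_urban)
    urban = np.array(
        [
            shapely.intersection(
                shapely.buffer(shapely.points(c), r, quad_segs=16), extent_poly
            )
            for c, r in zip(centers, radii)
        ],
        dtype=object,
    )
    population = np.maximum(
        1, np.round(shapely.area(urban) / 1e6 * density)
    ).astype(int)

    # facilities: a fraction clustered around towns, the rest uniform
    n_fac = lc_cfg.n_facilities
    n_clustered = int(round(lc_cfg.facility_urban_fraction * n_fac)) if n_fac else 0
    fac_xy = np.empty((0, 2))
    if n_clustered and lc_cfg.n_urban:
        town = rng.integers(0, lc_cfg.n_urban, n_clustered)
        offsets = rng.normal(0.0, 1.0, (n_clustered, 2)) * radii[town, None]
        fac_xy = centers[town] + offsets
    fac_xy = np.vstack([fac_xy, uniform_points(n_fac - len(fac_xy))])
    fac_xy[:, 0] = np.clip(fac_xy[:, 0], x0, x1)
    fac_xy[:, 1] = np.clip(fac_xy[:, 1], y0, y1)
    groups = rng.choice(list(lc_cfg.facility_groups), size=n_fac).astype(object)

    # make towns crop-free, as built-up land replaces cultivated land
    if lc_cfg.relabel_urban_landcover and len(urban):
        centroids = shapely.centroid(cells)
        tree = shapely.STRtree(urban)
        hit, _ = tree.query(centroids, predicate="intersects")
        categories[np.unique(hit)] = "NonCrop"

    return Landscape(
        extent=tuple(lc_cfg.extent),
        land_cover=cells,
        land_cover_category=np.asarray(categories, dtype=object),
        facilities=shapely.points(fac_xy),
        facility_group=groups,
        urban_areas=urban,
        urban_population=population,
        tracts=tracts,
        tract_ses=ses,
    )


# ---------------------------------------------------------------------------
# population

def generate_population(
    landscape: Landscape,
    n: int,
    config: PopulationConfig | StudyConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a control-pool of ``n`` residences.

    Residential density is ``urban_weight`` times higher inside town
    polygons than outside; sex, birth year and region follow the
    configured marginals; a configured fraction is flagged as having
    failed geocoding (``geocode_valid = False``).
    """
    if isinstance(config, StudyConfig):
        radius_m = config.radius_m
        config = config.population
    else:
        radius_m = 1000.0
    cfg = config or PopulationConfig()
    cfg.validate()
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = landscape.extent
    total_area = (x1 - x0) * (y1 - y0)

    urban_union = (
        shapely.unary_union(landscape.urban_areas)
        if len(landscape.urban_areas)
        else None
    )
    urban_area = shapely.area(urban_union) if urban_union is not None else 0.0
    w = cfg.urban_weight
    p_urban = (
        w * urban_area / (w * urban_area + (total_area - urban_area))
        if urban_area > 0
        else 0.0
    )

    in_town = rng.random(n) < p_urban
    xy = np.empty((n, 2))
    n_town = int(in_town.sum())
    if n_town:
        parts = (
            list(urban_union.geoms)
            if urban_union.geom_type == "MultiPolygon"
            else [urban_union]
        )
        areas = np.array([p.area for p in parts])
        pick = rng.choice(len(parts), size=n_town, p=areas / areas.sum())
        pts = np.empty((n_town, 2))
        for j in np.unique(pick):
            sel = pick == j
            pts[sel] = _sample_in_polygon(rng, parts[j], int(sel.sum()))
        xy[in_town] = pts
    n_out = n - n_town
    if n_out:
        out = np.empty((0, 2))
        while len(out) < n_out:
            m = max(int(1.5 * (n_out - len(out))), 32)
            cand = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
            if urban_union is not None:
                keep = ~shapely.contains_xy(urban_union, cand[:, 0], cand[:, 1])
                cand = cand[keep]
            out = np.vstack([out, cand])
        xy[~in_town] = out[:n_out]

    region_p = (
        np.asarray(cfg.region_weights, dtype=float)
        if cfg.region_weights is not None
        else np.full(len(cfg.regions), 1.0 / len(cfg.regions))
    )
    region_p = region_p / region_p.sum()
    region = rng.choice(list(cfg.regions), size=n, p=region_p).astype(object)
    sex = np.where(rng.random(n) < cfg.p_male, "M", "F").astype(object)
    birth_year = rng.integers(cfg.birth_years[0], cfg.birth_years[1] + 1, n)

    # per-region placement overrides (e.g. a crop-free, affluent region)
    for reg, profile in cfg.region_profiles.items():
        sel = np.flatnonzero(region == reg)
        if len(sel) == 0:
            continue
        xy[sel] = _profiled_locations(rng, landscape, profile, len(sel), radius_m)

    geocode_valid = rng.random(n) >= cfg.invalid_fraction

    return pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "sex": sex,
            "birth_year": birth_year,
            "region": region,
            "status": "control",
            "subgroup": None,
            "same_address": True,
            "geocode_valid": geocode_valid,
        }
    )


def _profiled_locations(rng, landscape, profile, n, radius_m):
    """Rejection-sample locations meeting a region profile."""
    x0, y0, x1, y1 = landscape.extent
    crop_polys, _ = landscape.crop_polygons()
    crop_tree = shapely.STRtree(crop_polys) if profile.get("crop_free") else None
    ses_median = float(np.median(landscape.tract_ses))
    high_tree = None
    if profile.get("high_ses"):
        mask = landscape.tract_ses >= ses_median
        high_tree = shapely.STRtree(landscape.tracts[mask])
    out = np.empty((0, 2))
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 1000:
            raise ConfigurationError("region profile cannot be satisfied")
        m = max(4 * (n - len(out)), 64)
        cand = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
        keep = np.ones(m, dtype=bool)
        pts = shapely.points(cand)
        if crop_tree is not None and len(crop_polys):
            near = crop_tree.query(pts, predicate="dwithin", distance=radius_m)[0]
            keep[np.unique(near)] = False
        if high_tree is not None:
            inside = high_tree.query(pts, predicate="intersects")[0]
            mask = np.zeros(m, dtype=bool)
            mask[np.unique(inside)] = True
            keep &= mask
        out = np.vstack([out, cand[keep]])
    return out[:n]


# ---------------------------------------------------------------------------
# outcomes

_ENV_ORDER = ("industrial", "intersection", "urban", "ring")
_SES_ORDER = ("Q2", "Q3", "Q4")


def linear_predictor(
    profiles: pd.DataFrame, params: TrueParams, region_effects: dict[str, float]
) -> np.ndarray:
    """Log-odds of case status under the generating model.

    ``profiles`` must carry columns gci, ses_q, env, sex, birth_year and
    region.  Birth year is centred at its mean before applying the
    per-year odds ratio.
    """
    eta = np.full(len(profiles), params.intercept, dtype=float)
    eta += np.log(params.or_gci_per10) * profiles["gci"].to_numpy(float) / 10.0
    ses_q = profiles["ses_q"].to_numpy()
    for level, orx in zip(_SES_ORDER, params.or_ses_q):
        eta += np.log(orx) * (ses_q == level)
    env = profiles["env"].to_numpy()
    for level, orx in zip(_ENV_ORDER, params.or_env):
        eta += np.log(orx) * (env == level)
    eta += np.log(params.or_sex) * (profiles["sex"].to_numpy() == "M")
    year = profiles["birth_year"].to_numpy(float)
    eta += np.log(params.or_year) * (year - year.mean())
    eta += profiles["region"].map(region_effects).to_numpy(float)
    return eta


def assign_outcomes(
    pool: pd.DataFrame,
    profiles: pd.DataFrame,
    params: TrueParams,
    n_cases: int,
    seed: int = 0,
    subgroup_shares: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample exactly ``n_cases`` cases from the pool.

    Each subject's case probability follows the logistic outcome model
    with a region intercept drawn once per region from N(0, region_sd²);
    cases are drawn without replacement with weight proportional to that
    probability (Gumbel top-k), restricted to validly geocoded subjects.
    Cases receive subgroup labels from the configured multinomial.

    Returns ``(cases, remaining_pool)``.
    """
    params.validate()
    if n_cases >= len(pool):
        raise ConfigurationError("n_cases must be smaller than the pool")
    if not pool["id"].to_numpy().shape == profiles["id"].to_numpy().shape or not (
        pool["id"].to_numpy() == profiles["id"].to_numpy()
    ).all():
        raise ConfigurationError("profiles must align 1:1 with the pool")
    rng = np.random.default_rng(seed)

    regions = sorted(pool["region"].unique())
    effects = {r: rng.normal(0.0, params.region_sd) for r in regions}
    merged = pool[["sex", "birth_year", "region"]].copy()
    for col in ("gci", "ses_q", "env"):
        merged[col] = profiles[col].to_numpy()
    eta = linear_predictor(merged, params, effects)
    p = expit(eta)
    valid = pool["geocode_valid"].to_numpy()
    with np.errstate(divide="ignore"):
        keys = np.where(valid, np.log(p), -np.inf) + rng.gumbel(size=len(pool))
    case_idx = np.argsort(keys)[-n_cases:]

    shares = subgroup_shares or dict(published.SUBGROUP_SHARES)
    labels = list(shares)
    p_lab = np.array([shares[k] for k in labels], dtype=float)
    p_lab = p_lab / p_lab.sum()

    cases = pool.iloc[np.sort(case_idx)].copy()
    cases["status"] = "case"
    cases["subgroup"] = rng.choice(labels, size=len(cases), p=p_lab)
    remaining = pool.drop(pool.index[np.sort(case_idx)])
    return cases, remaining
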