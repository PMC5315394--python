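"""Spatial containers and flat-file I/O.

The study works in a single planar metric frame; layers are exchanged as
GeoJSON FeatureCollections (properties ``category``, ``group``,
``population``, ``ses``) and subjects as CSV.  shapely provides all
geometry; no geodesy is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

SUBJECT_COLUMNS = [
    "id",
    "x",
    "y",
    "sex",
    "birth_year",
    "region",
    "status",
    "subgroup",
    "same_address",
    "geocode_valid",
]


@dataclass
class Landscape:
    """The four spatial layers of one study territory.

    ``land_cover`` and ``tracts`` each partition the rectangular
    ``extent``; ``facilities`` are points; ``urban_areas`` may overlap
    each other and any other layer.
    """

    extent: tuple[float, float, float, float]
    land_cover: np.ndarray  # array of shapely Polygons
    land_cover_category: np.ndarray  # array of str
    facilities: np.ndarray  # array of shapely Points
    facility_group: np.ndarray  # array of str
    urban_areas: np.ndarray  # array of shapely Polygons
    urban_population: np.ndarray  # array of int
    tracts: np.ndarray  # array of shapely Polygons
    tract_ses: np.ndarray  # array of float
    tract_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.tract_id is None:
            self.tract_id = np.array([f"T{i:04d}" for i in range(len(self.tracts))])

    @property
    def extent_polygon(self) -> Polygon:
        return shapely.box(*self.extent)

    def crop_polygons(self) -> tuple[np.ndarray, np.ndarray]:
        """Land-cover polygons that carry a crop label, with their labels."""
        mask = self.land_cover_category != "NonCrop"
        return self.land_cover[mask], self.land_cover_category[mask]

    def validate(self, rel_tol: float = 1e-6, overlap_tol: float = 1e-9) -> None:
        """Check the partition invariants of the land-cover and tract layers."""
        area = shapely.area(self.extent_polygon)
        for name, polys in (("land_cover", self.land_cover), ("tracts", self.tracts)):
            total = shapely.area(polys).sum()
            if abs(total - area) > rel_tol * area:
                raise ValueError(f"{name} does not cover the extent: {total} vs {area}")
            tree = shapely.STRtree(polys)
            i, j = tree.query(polys, predicate="intersects")
            sel = i < j
            if sel.any():
                inter = shapely.area(shapely.intersection(polys[i[sel]], polys[j[sel]]))
                if inter.max(initial=0.0) > overlap_tol * area:
                    raise ValueError(f"{name} polygons overlap")
        lo, hi = float(self.tract_ses.min()), float(self.tract_ses.max())
        if not np.isfinite([lo, hi]).all():
            raise ValueError("non-finite SES values")


# ---------------------------------------------------------------------------
# GeoJSON

def _feature_collection(geoms, props_list) -> dict:
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, props_list)
    ]
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path, geoms, props_list) -> None:
    with open(path, "w") as fh:
        json.dump(_feature_collection(geoms, props_list), fh, separators=(",", ":"))


def read_geojson(path) -> tuple[np.ndarray, list[dict]]:
    with open(path) as fh:
        fc = json.load(fh)
    geoms = np.array([shape(f["geometry"]) for f in fc["features"]], dtype=object)
    props = [f.get("properties") or {} for f in fc["features"]]
    return geoms, props


def write_landscape(landscape: Landscape, outdir) -> dict[str, str]:
    """Write the four layers as GeoJSON files; returns layer->path."""
    import os

    paths = {}
    layers = {
        "landcover": (landscape.land_cover,
                      [{"category": c} for c in landscape.land_cover_category]),
        "facilities": (landscape.facilities,
                       [{"group": g} for g in landscape.facility_group]),
        "urban": (landscape.urban_areas,
                  [{"population": int(p)} for p in landscape.urban_population]),
        "tracts": (landscape.tracts,
                   [{"ses": float(s), "tract_id": t}
                    for s, t in zip(landscape.tract_ses, landscape.tract_id)]),
    }
    for name, (geoms, props) in layers.items():
        path = os.path.join(outdir, f"{name}.geojson")
        write_geojson(path, geoms, props)
        paths[name] = path
    extent_path = os.path.join(outdir, "extent.json")
    with open(extent_path, "w") as fh:
        json.dump({"extent": list(landscape.extent)}, fh)
    paths["extent"] = extent_path
    return paths


def read_landscape(outdir) -> Landscape:
    import os

    lc, lc_props = read_geojson(os.path.join(outdir, "landcover.geojson"))
    fac, fac_props = read_geojson(os.path.join(outdir, "facilities.geojson"))
    urb, urb_props = read_geojson(os.path.join(outdir, "urban.geojson"))
    tr, tr_props = read_geojson(os.path.join(outdir, "tracts.geojson"))
    with open(os.path.join(outdir, "extent.json")) as fh:
        extent = tuple(json.load(fh)["extent"])
    return Landscape(
        extent=extent,
        land_cover=lc,
        land_cover_category=np.array([p["category"] for p in lc_props]),
        facilities=fac,
        facility_group=np.array([p["group"] for p in fac_props]),
        urban_areas=urb,
        urban_population=np.array([p["population"] for p in urb_props], dtype=int),
        tracts=tr,
        tract_ses=np.array([p["ses"] for p in tr_props], dtype=float),
        tract_id=np.array([p.get("tract_id", f"T{i:04d}")
                           for i, p in enumerate(tr_props)]),
    )


# ---------------------------------------------------------------------------
# Subjects CSV

def write_subjects(df: pd.DataFrame, path) -> None:
    out = df.loc[:, SUBJECT_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"id": str, "sex": str, "region": str, "status": str},
        keep_default_na=False,
        na_values=[""],
    )
    df["subgroup"] = df["subgroup"].where(df["subgroup"].notna(), None)
    for col in ("same_address", "geocode_valid"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def subject_points(df: pd.DataFrame) -> np.ndarray:
    return shapely.points(df["x"].to_numpy(float), df["y"].to_numpy(float))
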