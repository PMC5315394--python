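"""Study configuration objects.

A :class:`StudyConfig` pins down every threshold, radius, sample size and
seed of one pipeline run, so a run is a pure function of its config.
Configs round-trip through YAML/JSON for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import published

CROP_CATEGORIES = (
    "Irrigated",
    "Rice",
    "Vineyards",
    "Fruits",
    "Olives",
    "Heterogeneous",
)
NONCROP = "NonCrop"
LAND_CATEGORIES = CROP_CATEGORIES + (NONCROP,)

ENV_CATEGORIES = ("rural", "industrial", "intersection", "urban", "ring")


class ConfigurationError(ValueError):
    """Raised when a config violates a precondition."""


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic territory.

    The land-cover and census-tract layers are Voronoi tessellations of
    seeded Poisson point sets, so each layer partitions the rectangular
    extent exactly.  Land-cover cells under town polygons are relabelled
    NonCrop so that urban residents see little cultivated land, as in
    real land-cover inventories.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 50_000.0, 50_000.0)
    n_land_cells: int = 400
    category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "NonCrop": 0.50,
            "Irrigated": 0.20,
            "Heterogeneous": 0.10,
            "Fruits": 0.08,
            "Vineyards": 0.05,
            "Olives": 0.05,
            "Rice": 0.02,
        }
    )
    n_tracts: int = 250
    ses_range: tuple[float, float] = published.SES_RANGE
    n_facilities: int = 150
    facility_groups: tuple[str, ...] = (
        "metal production",
        "chemical industry",
        "food and beverage",
        "energy",
        "waste management",
        "cement and ceramics",
    )
    #: fraction of facilities clustered around towns (the rest uniform)
    facility_urban_fraction: float = 0.7
    n_urban: int = 12
    urban_radius_range: tuple[float, float] = (1_000.0, 6_000.0)
    #: people per km^2 used to assign town populations from town area
    urban_density_per_km2: float = 1_500.0
    relabel_urban_landcover: bool = True

    def validate(self) -> None:
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ConfigurationError(f"non-positive extent {self.extent}")
        if not self.category_weights:
            raise ConfigurationError("empty category weights")
        unknown = set(self.category_weights) - set(LAND_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown land categories {sorted(unknown)}")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category weights sum to {total}, not 1")
        if min(self.category_weights.values()) < 0:
            raise ConfigurationError("negative category weight")
        if self.n_land_cells < 1 or self.n_tracts < 1:
            raise ConfigurationError("need at least one land cell and one tract")


@dataclass
class PopulationConfig:
    """Marginals and spatial density of the simulated birth-registry pool."""

    n_pool: int = 25_000
    #: relative residential density inside town polygons vs outside
    urban_weight: float = 4.0
    invalid_fraction: float = published.INVALID_GEOCODE_FRACTION
    p_male: float = 0.5
    birth_years: tuple[int, int] = published.STUDY_YEARS
    regions: tuple[str, ...] = published.REGIONS
    #: region marginal; None means uniform
    region_weights: tuple[float, ...] | None = None
    #: per-region placement overrides, e.g. {"Basque Country":
    #: {"crop_free": True, "high_ses": True}} places that region's
    #: residents away from crops and in above-median-SES tracts
    region_profiles: dict[str, dict[str, bool]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_pool < 1:
            raise ConfigurationError("n_pool must be >= 1")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ConfigurationError("invalid_fraction must be in [0, 1)")
        if self.region_weights is not None and len(self.region_weights) != len(
            self.regions
        ):
            raise ConfigurationError("region_weights length mismatch")


@dataclass
class TrueParams:
    """Generating ('true') effects of the logistic outcome model.

    All effects are odds ratios; defaults are the published full-model
    point estimates for total CNS tumours, with unreported terms (sex,
    birth year, the 2-5 km ring) at the null.  ``intercept`` is the
    baseline log-odds and only sets the scale of case probabilities; the
    sampler draws a fixed number of cases, so it has no effect on study
    size.
    """

    intercept: float = -6.0
    or_gci_per10: float = published.TOTAL_CNS_OR["gci10"]
    or_ses_q: tuple[float, float, float] = (
        published.TOTAL_CNS_OR["ses_q2"],
        published.TOTAL_CNS_OR["ses_q3"],
        published.TOTAL_CNS_OR["ses_q4"],
    )
    #: industrial, intersection, urban, ring — each vs rural
    or_env: tuple[float, float, float, float] = (
        published.TOTAL_CNS_OR["env_industrial"],
        published.TOTAL_CNS_OR["env_intersection"],
        published.TOTAL_CNS_OR["env_urban"],
        1.0,
    )
    or_sex: float = 1.0
    or_year: float = 1.0
    region_sd: float = 0.25

    def validate(self) -> None:
        ors = (self.or_gci_per10, *self.or_ses_q, *self.or_env, self.or_sex, self.or_year)
        if any(v <= 0 for v in ors):
            raise ConfigurationError("all odds ratios must be strictly positive")
        if not np.isfinite(self.region_sd) or self.region_sd < 0:
            raise ConfigurationError("region_sd must be finite and >= 0")

    @classmethod
    def null(cls, region_sd: float = 0.0) -> "TrueParams":
        """All odds ratios at 1 (no exposure effects)."""
        return cls(
            or_gci_per10=1.0,
            or_ses_q=(1.0, 1.0, 1.0),
            or_env=(1.0, 1.0, 1.0, 1.0),
            or_sex=1.0,
            or_year=1.0,
            region_sd=region_sd,
        )


@dataclass
class StudyConfig:
    """Everything one end-to-end study run depends on."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    params: TrueParams = field(default_factory=TrueParams)
    n_cases: int = published.N_CASES
    ratio: int = published.MATCH_RATIO
    radius_m: float = published.BUFFER_RADIUS_METRES
    D_m: float = published.CHOSEN_D_METRES
    outer_m: float = published.OUTER_RING_METRES
    D_list: tuple[float, ...] = published.D_SWEEP_METRES
    urban_pop_threshold: int = 10_000
    quartile_reference: str = "controls"  # or "all"
    birth_year_window: int = 0
    #: fraction of cases whose diagnosis address differs from birth address
    mover_fraction: float = 1.0 - published.N_SAME_ADDRESS_CASES / published.N_CASES
    #: "flag": movers are only flagged (same_address=False);
    #: "relocate": movers additionally draw a fresh residence after the
    #: outcome, so their analysed exposure is decoupled from the one that
    #: generated their outcome.
    mover_mode: str = "flag"
    subgroup_shares: dict[str, float] = field(
        default_factory=lambda: dict(published.SUBGROUP_SHARES)
    )
    seed: int = 20_170_217

    def validate(self) -> None:
        self.landscape.validate()
        self.population.validate()
        self.params.validate()
        if self.n_cases < 1 or self.ratio < 1:
            raise ConfigurationError("n_cases and ratio must be >= 1")
        if self.n_cases * (1 + self.ratio) > self.population.n_pool:
            raise ConfigurationError("pool too small for n_cases at this ratio")
        for d in (self.radius_m, self.D_m, self.outer_m, *self.D_list):
            if d <= 0:
                raise ConfigurationError("all distances must be positive")
        if self.D_m > self.outer_m:
            raise ConfigurationError("D_m may not exceed outer_m")
        if self.quartile_reference not in ("controls", "all"):
            raise ConfigurationError("quartile_reference must be 'controls' or 'all'")
        if self.mover_mode not in ("flag", "relocate"):
            raise ConfigurationError("mover_mode must be 'flag' or 'relocate'")
        if not 0.0 <= self.mover_fraction <= 1.0:
            raise ConfigurationError("mover_fraction must be in [0, 1]")
        shares = sum(self.subgroup_shares.values())
        if abs(shares - 1.0) > 1e-9:
            raise ConfigurationError("subgroup shares must sum to 1")

    # -- seeds -----------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        kw: dict[str, Any] = {}
        if "landscape" in d:
            kw["landscape"] = _from_mapping(LandscapeConfig, d.pop("landscape"))
        if "population" in d:
            kw["population"] = _from_mapping(PopulationConfig, d.pop("population"))
        if "params" in d:
            kw["params"] = _from_mapping(TrueParams, d.pop("params"))
        kw.update(d)
        cfg = _from_mapping(cls, kw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _from_mapping(cls, mapping):
    """Build a dataclass, restoring tuple-typed fields from YAML lists."""
    kw = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in mapping.items():
        if key not in fields:
            raise ConfigurationError(f"unknown {cls.__name__} field {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kw[key] = value
    return cls(**kw)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
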