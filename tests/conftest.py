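import numpy as np
import pandas as pd
import pytest

from landepi.config import LandscapeConfig, PopulationConfig, StudyConfig


def small_config(**overrides) -> StudyConfig:
    """A fast, fully populated study config for tests.

    A 25 km square with ~150 land cells keeps geometry cheap; the
    birth-year range is narrowed so every matching stratum stays
    populated at a pool of a few thousand.
    """
    kw = dict(
        landscape=LandscapeConfig(
            extent=(0.0, 0.0, 25_000.0, 25_000.0),
            n_land_cells=150,
            n_tracts=100,
            n_facilities=25,
            n_urban=6,
        ),
        population=PopulationConfig(n_pool=6_000, birth_years=(2000, 2007)),
        n_cases=120,
        seed=20_200_101,
    )
    kw.update(overrides)
    return StudyConfig(**kw)


@pytest.fixture(scope="session")
def small_cfg() -> StudyConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_landscape(small_cfg):
    from landepi.synthetic_landscape import generate_landscape

    return generate_landscape(small_cfg, small_cfg.stage_seed("landscape"))


@pytest.fixture(scope="session")
def small_study(small_cfg):
    from landepi.study_pipeline import simulate_study

    return simulate_study(small_cfg)


def make_pool_frame(n: int, seed: int = 0, invalid_fraction: float = 0.0,
                    years=(1996, 2011)) -> pd.DataFrame:
    """A registry-like pool without geometry, for matching/model tests."""
    rng = np.random.default_rng(seed)
    regions = ("Aragon", "Basque Country", "Catalonia", "Madrid", "Navarre")
    return pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "sex": rng.choice(["M", "F"], n),
            "birth_year": rng.integers(years[0], years[1] + 1, n),
            "region": rng.choice(regions, n),
            "status": "control",
            "subgroup": None,
            "same_address": True,
            "geocode_valid": rng.random(n) >= invalid_fraction,
        }
    )
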