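import numpy as np
import pandas as pd
import pytest

from kinboost.panel import PanelConfig, Locus, default_panel
from kinboost.simulate import SimConfig, simulate_population, simulate_genotypes


def small_sim_config(seed: int = 42) -> SimConfig:
    """A scaled-down population keeping the study's structure."""
    return SimConfig(
        run_sizes={y: 300 for y in range(2008, 2020)},
        n_broodstock_dams=10,
        n_broodstock_sires=5,
        hatchery_mean_offspring=8.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def clean_panel():
    """Error-free, fully typed panel (for Mendelian oracles)."""
    return default_panel(error_rate=0.0, missing_rate=0.0)


@pytest.fixture(scope="session")
def small_population():
    cfg = small_sim_config()
    registry, truth = simulate_population(cfg)
    return cfg, registry, truth


@pytest.fixture(scope="session")
def small_genotypes(small_population, panel):
    _, registry, truth = small_population
    return simulate_genotypes(registry, truth, panel, seed=1)


@pytest.fixture(scope="session")
def clean_genotypes(small_population, clean_panel):
    _, registry, truth = small_population
    return simulate_genotypes(registry, truth, clean_panel, seed=1)


def founders_registry(n: int, year: int = 2010) -> pd.DataFrame:
    """A registry of unrelated individuals (no pedigree)."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "id": [f"{year}_{i:05d}" for i in range(n)],
            "return_year": year,
            "sex_true": rng.choice(["F", "M"], n),
            "sex_field": "F",
            "origin_true": "wild",
            "total_age": 4,
            "fw_age": 1,
            "return_doy": 200,
            "mefl_mm": 500.0,
            "scale_age": None,
            "is_broodstock": False,
        }
    )
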