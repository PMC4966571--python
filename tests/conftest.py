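"""Shared fixtures: small synthetic studies reused across test modules."""

from pathlib import Path

import pytest

from smallarea import SimulationConfig, simulate_study

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_study():
    """Two small cities with the default (non-null) effect structure."""
    cfg = SimulationConfig(n_cities=2, tracts_per_city=16, seed=101)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """One city with every effect switched off: theta = 1 everywhere."""
    cfg = SimulationConfig(
        n_cities=1,
        tracts_per_city=36,
        beta_true=(0.0, 0.0, 0.0, 0.0),
        sigma_b_true=(0.0, 0.0, 0.0, 0.0),
        sigma_s_true=0.0,
        sigma_h_true=0.0,
        sexes=("men",),
        seed=202,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def published_tertile_rows():
    """Printed city-level tertile ASMR comparisons (arithmetically
    self-consistent rows only) used to validate the table arithmetic."""
    import pandas as pd

    return pd.read_csv(DATA_DIR / "tertile_asmr_published.csv")
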