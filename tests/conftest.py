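"""Shared fixtures: small lattices, weights and synthetic panels."""

from pathlib import Path

import numpy as np
import pytest

import ahspatial as ah

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def grid9():
    """3x3 unit-cell lattice geometry."""
    return ah.generate_geometry(
        ah.SyntheticConfig(n_districts=9, n_years=2, cell_size_km=1.0)
    )


@pytest.fixture(scope="session")
def queen9(grid9):
    return ah.queen_contiguity(list(zip(grid9.district_ids, grid9.polygons)))


@pytest.fixture(scope="session")
def grid16():
    """4x4 lattice used in the recovery simulations."""
    return ah.generate_geometry(ah.SyntheticConfig(n_districts=16, n_years=4))


@pytest.fixture(scope="session")
def queen16(grid16):
    return ah.queen_contiguity(list(zip(grid16.district_ids, grid16.polygons)))


@pytest.fixture(scope="session")
def grid117():
    return ah.generate_geometry(ah.SyntheticConfig())


@pytest.fixture(scope="session")
def queen117(grid117):
    return ah.queen_contiguity(list(zip(grid117.district_ids, grid117.polygons)))


@pytest.fixture(scope="session")
def default_panel(queen117):
    """One default-config synthetic panel with its truth."""
    cfg = ah.SyntheticConfig(seed=12345)
    panel, truth = ah.generate_panel(cfg, queen117)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def demeaned_panel(default_panel):
    _, panel, _ = default_panel
    return ah.within_transform(panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(20080101)


@pytest.fixture(scope="session")
def toy_discharge_path():
    return DATA_DIR / "toy_discharges.csv"
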