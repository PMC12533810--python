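import numpy as np
import pandas as pd
import pytest

from smokewave import (
    ConcentrationField,
    Emissions,
    Grid,
    Meteorology,
    ScenarioEnsemble,
    ScenarioLabel,
    SyntheticConfig,
)
from smokewave.grids import FACTORIAL_LABELS


@pytest.fixture
def grid():
    return Grid(nrows=6, ncols=8, dx=12.0, dy=12.0, x0=6.0, y0=6.0)


@pytest.fixture
def days():
    return pd.date_range("2023-06-06", periods=3, freq="D")


def field_from(values, grid, days, scenario="test"):
    return ConcentrationField(np.asarray(values, dtype=float), days, grid, scenario)


@pytest.fixture
def make_field(grid, days):
    def _make(values, scenario="test"):
        return field_from(values, grid, days, scenario)

    return _make


@pytest.fixture
def random_ensemble(grid, days):
    """Four random factorial members on the shared small grid."""
    rng = np.random.default_rng(20230606)
    members = {
        lab: field_from(
            rng.uniform(1.0, 120.0, size=(len(days), grid.nrows, grid.ncols)),
            grid,
            days,
            lab,
        )
        for lab in FACTORIAL_LABELS
    }
    return ScenarioEnsemble(members)


def additive_ensemble(grid, days, base=50.0, emis=None, met=None):
    """Ensemble with no emissions x meteorology interaction.

    member(e, m) = base + emis[e] + met[m], each injected term a full
    (day, row, col) array.
    """
    rng = np.random.default_rng(7)
    shape = (len(days), grid.nrows, grid.ncols)
    if emis is None:
        emis = {
            Emissions.CAMS: rng.uniform(-8.0, 8.0, shape),
            Emissions.QFED: rng.uniform(-8.0, 8.0, shape),
        }
    if met is None:
        met = {
            Meteorology.FNL: rng.uniform(-4.0, 4.0, shape),
            Meteorology.NAM: rng.uniform(-4.0, 4.0, shape),
        }
    members = {
        lab: field_from(
            base + emis[lab.emissions] + met[lab.meteorology], grid, days, lab
        )
        for lab in FACTORIAL_LABELS
    }
    return ScenarioEnsemble(members), emis, met


@pytest.fixture
def small_cfg():
    """Scaled-down synthetic conditions for fast structural tests."""
    return SyntheticConfig(
        nrows=20,
        ncols=30,
        plume_start=(8.0, 5.0),
        plume_step=(1.0, 8.0),
        county_blocks=(4, 5),
        n_monitors=10,
        seed=7,
    )
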