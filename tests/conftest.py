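"""Shared fixtures: small hand-built censuses and a default synthetic study."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from spastab.synthetic_data import StudyDesign, SyntheticTruth, generate_study

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


def make_trees(rows) -> pd.DataFrame:
    """Build a typed tree table from (site, plot, subplot, species, dbh, height)."""
    df = pd.DataFrame(
        rows, columns=["site_id", "plot_id", "subplot_id", "species", "dbh_cm", "height_m"]
    )
    df["subplot_id"] = df["subplot_id"].astype("int64")
    df["dbh_cm"] = df["dbh_cm"].astype(float)
    df["height_m"] = df["height_m"].astype(float)
    return df


@pytest.fixture
def toy_plot_trees() -> pd.DataFrame:
    """Two-species plot with hand-checkable statistics.

    Species A: 3 stems of DBH 10 in subplots 1, 2, 3.
    Species B: 1 stem of DBH 20 in subplot 1.
    All other subplots empty. Heights complete.
    """
    return make_trees(
        [
            ("S1", "P1", 1, "A", 10.0, 8.0),
            ("S1", "P1", 2, "A", 10.0, 9.0),
            ("S1", "P1", 3, "A", 10.0, 10.0),
            ("S1", "P1", 1, "B", 20.0, 15.0),
        ]
    )


@pytest.fixture
def toy_plots() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "plot_id": ["P1"],
            "site_id": ["S1"],
            "x_km": [0.0],
            "y_km": [0.0],
            "elevation_m": [100.0],
        }
    )
    df.attrs["coordinate_mode"] = "planar"
    return df


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (129 plots), shared across tests."""
    return generate_study(StudyDesign(), SyntheticTruth(), seed=20250925 % 7919)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
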