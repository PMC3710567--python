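import numpy as np
import pandas as pd
import pytest

from ltsseff import JURISDICTIONS, PanelDataset


def make_row(state="WY", year=1999, **overrides):
    row = {
        "state": state,
        "year": year,
        "total_cost": 1.0e9,
        "q_inst": 20_000.0,
        "q_hcbs": 30_000.0,
        "hcbs_share": 60.0,
        "waiver_share": 50.0,
        "icfmr_share": 5.0,
        "managed_care": 0,
        "con": 1,
        "population": 1_000_000.0,
        "pc_income": 33_000.0,
        "unemployment": 4.5,
    }
    row.update(overrides)
    return row


def make_frame(pairs, **overrides):
    """Frame with one valid row per (state, year) pair."""
    return pd.DataFrame([make_row(s, y, **overrides) for s, y in pairs])


@pytest.fixture
def toy_dataset():
    pairs = [("CA", y) for y in (1999, 2000, 2001)] + [("NY", y) for y in (1999, 2000, 2001)]
    return PanelDataset(make_frame(pairs))


@pytest.fixture
def full_grid():
    """Complete 51-jurisdiction x 9-year panel (1999-2007)."""
    pairs = [(s, y) for s in JURISDICTIONS for y in range(1999, 2008)]
    return PanelDataset(make_frame(pairs))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
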