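import numpy as np
import pandas as pd
import pytest

import phenosync as ps


@pytest.fixture(scope="session")
def small_cfg():
    """A down-scaled woodland: 6x6 pixels, 6 springs, 150 nestboxes."""
    return ps.SimulationConfig(grid_rows=6, grid_cols=6, n_years=6,
                               n_nestboxes=150, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return ps.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def truth_table(small_bundle):
    """Analysis table built from truth green-up (no satellite noise)."""
    b = small_bundle
    tab = b.breeding.merge(
        b.landscape.nestboxes[["box_id", "pixel_id", "altitude",
                               "edge_distance", "oak_density_75m"]], on="box_id")
    tab, _ = ps.filter_first_broods(tab)
    truth = b.greenup.as_frame().set_index(["pixel_id", "year"])["true_greenup"]
    tab["greenup"] = truth.reindex(
        pd.MultiIndex.from_frame(tab[["pixel_id", "year"]])).to_numpy()
    return tab


@pytest.fixture(scope="session")
def truth_greenup_map(small_bundle):
    gmap = small_bundle.greenup.as_frame().rename(
        columns={"true_greenup": "greenup_day"})
    gmap["converged"] = True
    return gmap


def double_logistic(day, greenup=110.0, senescence=280.0, base=0.2, amp=0.4,
                    rate=0.1):
    """Reference seasonal EVI2 curve used as ground truth in smoother tests."""
    day = np.asarray(day, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-rate * (day - greenup)))
    fall = 1.0 / (1.0 + np.exp(-rate * (day - senescence)))
    return base + amp * (rise - fall)


@pytest.fixture(scope="session")
def midpoints():
    return np.arange(4, 365, 8.0)
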