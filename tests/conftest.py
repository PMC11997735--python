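import warnings

import numpy as np
import pandas as pd
import pytest

from mpatrack import synthetic_data as sd

warnings.filterwarnings("ignore", category=UserWarning)

#: light boosting settings for tests that exercise machinery, not the
#: fixed production hyperparameters
LIGHT_HP = {"n_trees": 200, "learning_rate": 0.05, "tree_complexity": 3}


@pytest.fixture(scope="session")
def world():
    """Shared small fixture world: 20x20 deg grid, 3 monthly layers."""
    return sd.fixture_world(seed=11, months=3)


@pytest.fixture(scope="session")
def world12():
    """Full-year fixture world for seasonal/scenario tests."""
    return sd.fixture_world(seed=11, months=12)


def make_track(lons, lats, t0="2022-06-01", dt_s=3600, depth=None, iid="x1",
               species="testfish"):
    """Assemble a RawTrack from coordinate lists."""
    from mpatrack.track_processing import RawTrack
    n = len(lons)
    ts = pd.date_range(t0, periods=n, freq=pd.Timedelta(seconds=dt_s), tz="UTC")
    df = pd.DataFrame({"timestamp": ts, "lon": lons, "lat": lats})
    if depth is not None:
        df["depth_m"] = depth
    return RawTrack(df, iid, species)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
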