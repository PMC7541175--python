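import numpy as np
import pandas as pd
import pytest

from pathsel.grid import Grid


@pytest.fixture
def template_grid():
    """20x20 empty grid, 30 m cells, origin at (0, 600)."""
    return Grid(np.zeros((20, 20)), origin_x=0.0, origin_y=600.0, cell_size=30.0, crs_tag="test")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def hourly_fixes(animal, start, xy, elev=None):
    """Build a telemetry frame with hourly timestamps from vertex list xy."""
    xy = np.asarray(xy, dtype=float)
    times = pd.date_range(start, periods=len(xy), freq="h")
    return pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": times,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "elev": elev if elev is not None else np.full(len(xy), np.nan),
        }
    )


@pytest.fixture
def make_hourly_fixes():
    return hourly_fixes
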