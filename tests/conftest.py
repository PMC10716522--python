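import numpy as np
import pandas as pd
import pytest

from scspamet import synthetic_data as sd
from scspamet.io_formats import CellTable, ChannelPanel, IonImageStack, MarkerImageStack


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-cell lung-like tissue with moderate noise (session-cached)."""
    return sd.simulate_dataset(n_cells=300, field_um=380.0, seed=11, dispersion=0.2)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """A 250-cell tissue with zero noise, for planted-effect identities."""
    return sd.simulate_dataset(n_cells=250, field_um=340.0, seed=5, dispersion=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_ion_stack(rng, c=3, h=8, w=8, pixel_size=1.0):
    names = [f"mz_{i}" for i in range(c)]
    panel = ChannelPanel.from_names(names, "metabolite", mz=np.arange(1, c + 1))
    data = rng.uniform(0, 10, size=(c, h, w))
    return IonImageStack(data, panel, pixel_size)


def random_marker_stack(rng, c=3, h=8, w=8, pixel_size=1.0):
    names = [f"m{i}" for i in range(c)]
    panel = ChannelPanel.from_names(names, "protein")
    data = rng.uniform(0, 10, size=(c, h, w))
    return MarkerImageStack(data, panel, pixel_size)


def make_cell_table(xy, **channels):
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(xy) + 1),
            "centroid_x_um": xy[:, 0],
            "centroid_y_um": xy[:, 1],
        }
    )
    for name, vals in channels.items():
        df[name] = np.asarray(vals, dtype=float)
    return CellTable(df)
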