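import numpy as np
import pytest

from geldiff.imaging import GelGeometry, ImageSeries
from geldiff.synthetic import SimulationParams, simulate_experiment


@pytest.fixture(scope="session")
def five_cell_params():
    """Small rendered chip: five well-separated cells on a 200 µm-wide strip."""
    positions = [(60.0, 300.0), (140.0, 700.0), (70.0, 1200.0), (150.0, 1600.0), (100.0, 1900.0)]
    return SimulationParams(
        d_true=300.0,
        n_cells=5,
        cell_positions_um=positions,
        image_width_um=200.0,
        n_frames=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def five_cell_chip(five_cell_params):
    return simulate_experiment(five_cell_params)


@pytest.fixture(scope="session")
def full_geometry():
    """Geometry of the standard 3 mm gel with the default fit interval."""
    return GelGeometry(
        y_donor_interface=0.0,
        y_acceptor_interface=3000.8136,  # 2400 pixels of 1.250339 µm
        y_lower_boundary=150.04068,  # 120 pixels
        y_upper_boundary=3000.8136,
    )


def make_series(frames_by_channel, pixel_size_um=1.0, t_lag_s=60.0, interval_s=60.0):
    """ImageSeries from raw per-channel (T, Y, X) arrays."""
    n = next(iter(frames_by_channel.values())).shape[0]
    return ImageSeries(
        channels={k: np.asarray(v) for k, v in frames_by_channel.items()},
        pixel_size_um=pixel_size_um,
        timestamps_s=t_lag_s + interval_s * np.arange(n),
        t_lag_s=t_lag_s,
    )
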