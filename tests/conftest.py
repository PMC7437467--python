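import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aqpflux.io_trajectory import Topology, Trajectory
from aqpflux.synthetic import (
    BilayerConfig,
    ChannelWaterConfig,
    FilterConfig,
    gen_bilayer,
    gen_channel_water,
    gen_filter,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_channel_system():
    """4 channels x 8 waters, 2001 frames at 1 ps: ten 200-ps windows/channel."""
    return gen_channel_water(ChannelWaterConfig(n_frames=2001, seed=11))


@pytest.fixture(scope="session")
def bilayer_system():
    return gen_bilayer(BilayerConfig(seed=11))


@pytest.fixture(scope="session")
def filter_system():
    return gen_filter(FilterConfig(n_frames=2000, seed=11))


@pytest.fixture
def tiny_topology():
    """Mixed topology: 2 waters, 2 P lipids, one 3-atom protein residue."""
    return Topology(
        atom_name=["OH2", "OH2", "P", "P", "CA", "CB", "CG"],
        residue_name=["TIP3", "TIP3", "POPC", "POPC", "PHE", "PHE", "PHE"],
        residue_number=[1, 2, 3, 4, 43, 43, 43],
        chain_id=["W", "W", "M", "M", "A", "A", "A"],
    )


def make_trajectory(coords, box=(100.0, 100.0, 100.0), dt=1.0):
    coords = np.asarray(coords, dtype=np.float32)
    return Trajectory(coords=coords, box=np.asarray(box, dtype=float), dt_frame=dt)
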