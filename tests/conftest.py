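import numpy as np
import pytest

from vibronet import synthetic as syn
from vibronet.trajectory import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_traj():
    """10-residue zig-zag Cα chain, 5 frames, no velocities."""
    base = np.zeros((10, 3))
    base[:, 0] = np.arange(10) * 3.8
    base[:, 1] = (np.arange(10) % 2) * 1.0
    base[:, 2] = (np.arange(10) % 3) * 0.5
    coords = np.stack([base + 0.01 * f for f in range(5)])
    return Trajectory.from_arrays(
        coords=coords,
        dt=100.0,
        elements=["C"] * 10,
        names=["CA"] * 10,
        resids=list(range(10)),
        resnames=["ALA"] * 10,
    )


@pytest.fixture(scope="session")
def fragment_switch_run():
    """One mid-sized fragment-switch trajectory shared across tests."""
    spec = syn.SyntheticSpec(n_frames=3000, dt=100.0, n_residues=40, seed=2)
    return syn.generate_fragment_switch_trajectory(spec)
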