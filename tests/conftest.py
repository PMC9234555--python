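import numpy as np
import pytest

from confdyn.synthetic_data import (
    GaussianTrajectorySpec,
    TwoStateSpec,
    ca_topology,
    generate_gaussian_trajectory,
    generate_two_state,
    helix_structure,
)
from confdyn.trajectory_core import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gaussian_traj():
    """10 residues, one correlated block (1-5, rho=0.8), 2000 frames."""
    spec = GaussianTrajectorySpec(
        n_residues=10, blocks=[(1, 5)], rho=0.8, n_frames=2000, seed=7
    )
    return generate_gaussian_trajectory(spec), spec


@pytest.fixture
def two_state():
    spec = TwoStateSpec(n_residues=30, n_frames=3000, seed=3)
    traj, labels = generate_two_state(spec)
    return traj, labels, spec


@pytest.fixture
def static_traj():
    """Five identical frames of a 12-residue helix."""
    ref = helix_structure(12)
    coords = np.repeat(ref[None], 5, axis=0)
    return Trajectory(ca_topology(12), coords, np.arange(5.0))
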