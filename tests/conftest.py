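import numpy as np
import pytest

from pcmrheo import MediumModel, RenderConfig, SimConfig, simulate_trajectories

# Printed condensate rheology conditions: zero-shear viscosity (Pa·s)
# and terminal relaxation time (s) for the kinase-active and
# kinase-dead scaffold preparations.
CA_ETA0, CA_TAU = 31.8, 4.6
KD_ETA0, KD_TAU = 3.8, 1.03


@pytest.fixture(scope="session")
def ca_medium() -> MediumModel:
    return MediumModel.maxwell(CA_ETA0, CA_TAU)


@pytest.fixture(scope="session")
def kd_medium() -> MediumModel:
    return MediumModel.maxwell(KD_ETA0, KD_TAU)


@pytest.fixture(scope="session")
def bead_grid_trajectories():
    """Five beads on a grid in a low-viscosity Newtonian medium.

    Per-frame steps are ~0.8 px at 0.1 µm/px so localization error is
    small relative to motion; used by rendering/tracking round trips.
    """
    medium = MediumModel.newtonian(0.02)
    starts = np.array([[2.4, 2.4], [2.4, 7.2], [7.2, 2.4], [7.2, 7.2], [4.8, 4.8]])
    traj = simulate_trajectories(
        medium,
        SimConfig(n_beads=5, n_frames=100, dt=0.015, seed=2),
        initial_positions_um=starts,
    )
    return medium, traj


@pytest.fixture(scope="session")
def render_hi_snr() -> RenderConfig:
    return RenderConfig(image_shape=(96, 96), peak_signal=5000.0, background=100.0)
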