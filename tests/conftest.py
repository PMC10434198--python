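import numpy as np
import pytest

from swarmphage import Calibration, Trajectory, TrajectoryEnsemble
from swarmphage.synth import TrajectoryGenParams, gen_trajectories


@pytest.fixture
def cal():
    return Calibration(pixel_size=0.1, frame_interval=3.0)


@pytest.fixture
def small_brownian():
    """A modest Brownian ensemble for I/O and invariance tests."""
    ensemble, truth = gen_trajectories(
        TrajectoryGenParams(model="brownian", D=0.041, dt=3.0, n_steps=60,
                            n_particles=40, seed=7)
    )
    return ensemble, truth


def straight_track(v_um_s: float, dt: float, n: int, track_id: str = "0") -> Trajectory:
    t = np.arange(n) * dt
    return Trajectory(track_id=track_id, frames=np.arange(n), t=t,
                      x=v_um_s * t, y=np.zeros(n))


@pytest.fixture
def ballistic_ensemble():
    traj = straight_track(1.0, 1.0, 41)
    return TrajectoryEnsemble([traj], Calibration(pixel_size=1.0, frame_interval=1.0))


@pytest.fixture
def stationary_ensemble():
    n = 10
    traj = Trajectory(track_id="0", frames=np.arange(n), t=np.arange(n, dtype=float),
                      x=np.full(n, 2.5), y=np.full(n, -1.0))
    return TrajectoryEnsemble([traj], Calibration(pixel_size=1.0, frame_interval=1.0))
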