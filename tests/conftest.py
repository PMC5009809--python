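import numpy as np
import pytest

from nkcontacts.trackio import FieldOfView, Trajectory


def make_track(cell_id, cell_type, xyz, dt_s=30.0, frames=None):
    """Trajectory from a coordinate list; times follow the frame clock."""
    xyz = np.asarray(xyz, dtype=float)
    if frames is None:
        frames = np.arange(len(xyz))
    frames = np.asarray(frames)
    return Trajectory(cell_id, cell_type, frames, frames * dt_s, xyz)


def random_track(rng, cell_id="NK000", cell_type="NK", n=30, step_um=4.0, dt_s=30.0):
    """Random-walk track: i.i.d. Gaussian 3D steps of scale step_um."""
    steps = rng.normal(scale=step_um / np.sqrt(3), size=(n - 1, 3))
    xyz = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    return make_track(cell_id, cell_type, xyz, dt_s=dt_s)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_fov():
    """Two NK cells and one DC; NK000 sits on the DC, NK001 is far away."""
    n = 12
    still = np.tile([50.0, 50.0, 20.0], (n, 1))
    still = still + np.linspace(0, 0.5, n)[:, None]  # sub-μm creep
    far = np.tile([500.0, 500.0, 20.0], (n, 1))
    far[:, 0] += np.arange(n) * 5.0
    dc = np.tile([51.0, 50.0, 20.0], (n, 1))
    return FieldOfView(
        fov_id="FOV000",
        condition="steady_state",
        frame_interval_s=30.0,
        trajectories=[
            make_track("NK000", "NK", still),
            make_track("NK001", "NK", far),
            make_track("DC000", "DC", dc),
        ],
    )
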