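import numpy as np
import pytest

from rmtrack import SimulationParams, SpheroidGeometry, Track, TrackSet, simulate_trackset


@pytest.fixture
def spheroid():
    return SpheroidGeometry(0.0, 0.0, 50.0)


@pytest.fixture
def simple_trackset():
    """Two well-formed tracks in µm, frame interval 1 min."""
    t1 = Track("a", frames=[0, 1, 2], x=[0.0, 3.0, 3.0], y=[0.0, 4.0, 9.0])
    t2 = Track("b", frames=[0, 1, 2, 3], x=[10.0, 8.0, 6.0, 4.0], y=[0.0] * 4)
    return TrackSet(tracks=[t1, t2], frame_interval=1.0, pixel_size=1.0)


@pytest.fixture(scope="session")
def default_cohort():
    """A moderate cohort under default study conditions (seeded)."""
    params = SimulationParams(n_cells=60, seed=7)
    ts, gt = simulate_trackset(params)
    return params, ts, gt


def random_track(rng: np.random.Generator, n: int, cell_id: str = "r",
                 gaps: bool = False) -> Track:
    """A random-walk track, optionally with frame gaps."""
    if gaps:
        frames = np.sort(rng.choice(np.arange(3 * n), size=n, replace=False))
    else:
        frames = np.arange(n)
    steps = rng.normal(0, 3.0, size=(n, 2))
    pos = np.cumsum(steps, axis=0)
    return Track(cell_id, frames=frames, x=pos[:, 0], y=pos[:, 1])
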