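import numpy as np
import pytest

from poremap import FrameSeries, PoreSimParams, SiteMeta, make_pore_trajectory


def make_frames(coords, box=(100.0, 100.0, 100.0), dt=1.0, resnames=None, atoms=None):
    """Build a FrameSeries from an (f, s, 3) array and a constant (or per-frame) box."""
    coords = np.asarray(coords, dtype=float)
    f, s, _ = coords.shape
    box = np.asarray(box, dtype=float)
    if box.ndim == 1:
        box = np.tile(box, (f, 1))
    sites = [
        SiteMeta(
            resid=i + 1,
            resname=(resnames[i] if resnames else "RES"),
            atom=(atoms[i] if atoms else "X"),
        )
        for i in range(s)
    ]
    return FrameSeries(times=dt * np.arange(f), coords=coords, box=box, sites=sites)


@pytest.fixture(scope="session")
def default_pore():
    """Default synthetic poration trajectory (seed 0) with its ground truth."""
    return make_pore_trajectory(PoreSimParams(seed=0))


@pytest.fixture
def static_traj():
    """3 static collinear sites in a large box, 5 frames."""
    frame = np.array([[0.0, 0, 0], [5.0, 0, 0], [9.0, 0, 0]])
    return make_frames(np.tile(frame, (5, 1, 1)))
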