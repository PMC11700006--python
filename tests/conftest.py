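import numpy as np
import pytest

from cardiotrack import gdc, synthdata as sd
from cardiotrack.params import TrajectoryParams, sequence_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_image(rng):
    """Smooth random texture in [0, 1], the kind of structured content
    local-correlation registration needs everywhere in the frame."""
    from scipy import ndimage
    img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 3.0)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def lv_tracked_small():
    """A short beating-LV cine with ground-truth landmark tracks and the
    corresponding registration-derived tracks (shared across tests
    because landmark propagation is the expensive step)."""
    seq = sequence_preset("bSSFP", "coronal")
    # fast breathing (2 s period) so the 40-frame series spans ~2 cycles
    # and a train-first half still covers the full motion range
    traj = sd.make_trajectory(TrajectoryParams(
        resp_p2p_mm=15.0, cardiac_p2p_mm=0.0, resp_rate_bpm=30.0,
        duration_s=6.0))
    cine, truth = sd.render_lv_cine(
        traj, sd.cos4_phase(70.0), seq, seed=0, n_frames=40)
    tracks = gdc.track_landmarks(cine, truth, gdc.RegistrationConfig())
    return {"cine": cine, "truth": truth, "tracks": tracks, "seq": seq}
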