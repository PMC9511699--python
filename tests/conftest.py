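import numpy as np
import pytest
from hypothesis import settings

import frameindep as fi

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast three-group phantom: 3 cases x 8 frames x 5 ROIs per group."""
    return fi.PhantomConfig(
        cases_per_group=3,
        frames_per_case=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return fi.generate_cohort(tiny_config)


def constant_sequence(value=100, n_frames=3, size=(32, 32), case_id="c0", group="g"):
    frames = np.full((n_frames, *size), value, dtype=np.uint8)
    return fi.ImageSequence(case_id=case_id, group=group, frames=frames)


def grid_rois(n=2, w=8, h=8, n_frames=3):
    rois = [fi.ROI(roi_id=k, x=k * w, y=0, w=w, h=h) for k in range(n)]
    return fi.ROISet.broadcast(rois, n_frames)
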