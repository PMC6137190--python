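import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clear_scene():
    """Short clear-water sequence with no corrupted frames."""
    from fincount.synthetic import SceneConfig, generate_sequence

    cfg = SceneConfig(
        n_frames=40,
        error_frame_probability=0.0,
        ptz_wrong_probability=0.0,
        rng_seed=7,
    )
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def square_roi():
    """A single RoI whose component is an exact 50x50 square."""
    from datetime import datetime

    from fincount.io import FrameRecord
    from fincount.segmentation import extract_rois

    mask = np.zeros((120, 120), dtype=bool)
    mask[30:80, 40:90] = True
    frame = FrameRecord(
        frame_id="sq",
        timestamp=datetime(2013, 1, 1),
        _pixels=np.full((120, 120), 100, dtype=np.uint8),
    )
    (roi,) = extract_rois(mask, frame, min_blob_area=50)
    return roi


def make_roi_from_mask(mask, pixels=None):
    """Build the unique RoI of a single-component binary mask."""
    from datetime import datetime

    from fincount.io import FrameRecord
    from fincount.segmentation import extract_rois

    if pixels is None:
        pixels = np.full(mask.shape, 100, dtype=np.uint8)
    frame = FrameRecord(
        frame_id="m", timestamp=datetime(2013, 1, 1), _pixels=pixels.astype(np.uint8)
    )
    rois = extract_rois(mask, frame, min_blob_area=1)
    assert len(rois) == 1
    return rois[0]
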