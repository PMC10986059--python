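import numpy as np
import pytest

from chorioquant import SceneParams


@pytest.fixture
def small_scene_params():
    """Compact B-scan scene (3-mm ROI at half resolution) for fast tests."""
    def make(**overrides):
        base = dict(
            image_width_px=400,
            image_height_px=160,
            lateral_um_per_px=11.72,
            axial_um_per_px=3.9,
            choroid_thickness_um=240.0,
            upper_boundary_row=30,
            roi_width_mm=3.0,
            vessel_radius_range_um=(15.0, 50.0),
            seed=0,
        )
        base.update(overrides)
        return SceneParams(**base)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
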