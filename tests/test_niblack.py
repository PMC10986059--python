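import numpy as np
import pytest
from skimage.filters import threshold_niblack

from chorioquant import NiblackParams, niblack_binarize


def _disk_image(n=256, bg=200.0, fg=40.0, centers=((64, 64), (180, 120)), r=6):
    img = np.full((n, n), bg)
    mask = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]
    for cy, cx in centers:
        d = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask |= d
    img[mask] = fg
    return img, mask


@pytest.mark.parametrize("k", [0.0, -0.2, -1.0])
def test_constant_image_yields_empty_mask(k):
    """Tie contract: intensity == threshold is stroma, so a flat image has
    no lumen for any k <= 0."""
    img = np.full((64, 64), 123.0)
    region = np.ones_like(img, dtype=bool)
    out = niblack_binarize(img, region, NiblackParams(window_px=15, k=k))
    assert not out.any()


def test_dark_disks_match_global_threshold_oracle():
    """With a window much larger than the disks and k=0, the local method
    reduces to thresholding at the (regional) mean."""
    img, disks = _disk_image()
    region = np.ones_like(img, dtype=bool)
    out = niblack_binarize(img, region, NiblackParams(window_px=201, k=0.0))
    # brute-force global-threshold oracle
    oracle = img < img.mean()
    assert np.array_equal(out, disks)
    assert np.array_equal(out, oracle)


@pytest.mark.parametrize("c", [0.5, 2.3])
def test_scale_invariance(c):
    rng = np.random.default_rng(0)
    img = rng.uniform(20, 220, size=(96, 96))
    region = np.ones_like(img, dtype=bool)
    p = NiblackParams(window_px=31, k=-0.2)
    assert np.array_equal(
        niblack_binarize(img, region, p), niblack_binarize(c * img, region, p)
    )


def test_matches_skimage_on_full_mask_interior():
    """Independent oracle: with a full rectangular mask the masked statistics
    equal ordinary windowed statistics away from the borders (skimage's
    sign convention for k is opposite)."""
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 255, size=(128, 128))
    region = np.ones_like(img, dtype=bool)
    w, k = 25, -0.2
    mine = niblack_binarize(img, region, NiblackParams(window_px=w, k=k))
    ref_thresh = threshold_niblack(img, window_size=w, k=-k)
    ref = img < ref_thresh
    m = w // 2 + 1
    assert np.array_equal(mine[m:-m, m:-m], ref[m:-m, m:-m])


def test_statistics_restricted_to_region():
    """Pixels outside the mask must not influence the threshold: flooding
    the surroundings with extreme values changes nothing."""
    img, _ = _disk_image(n=128, centers=((64, 64),))
    region = np.zeros_like(img, dtype=bool)
    region[32:96, 32:96] = True
    p = NiblackParams(window_px=61, k=0.0)
    out1 = niblack_binarize(img, region, p)
    img2 = img.copy()
    img2[~region] = 10000.0
    out2 = niblack_binarize(img2, region, p)
    assert np.array_equal(out1, out2)
    assert not out1[~region].any()


def test_errors():
    img = np.zeros((32, 32))
    with pytest.raises(ValueError, match="empty"):
        niblack_binarize(img, np.zeros_like(img, dtype=bool), NiblackParams(15, 0.0))
    with pytest.raises(ValueError, match="fit"):
        niblack_binarize(img, np.ones_like(img, dtype=bool), NiblackParams(45, 0.0))
    with pytest.raises(ValueError):
        NiblackParams(window_px=10)
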