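import numpy as np
import pytest

from chorioquant import (
    AngioParams,
    EnFaceAngio,
    FdThresholdSpec,
    SlabSpec,
    compute_ccfd,
    generate_cc_enface,
    project_cc_slab,
)


def _enface(arr, lat=5.86):
    return EnFaceAngio(image=np.asarray(arr, dtype=float), lateral_um_per_px=lat)


class TestComputeCcfd:
    def test_bright_image_has_zero_deficit(self):
        res = compute_ccfd(_enface(np.full((512, 512), 45.0)))
        assert res.ccfd_pct == 0.0  # ties count as perfused

    def test_dark_image_is_all_deficit(self):
        res = compute_ccfd(_enface(np.zeros((512, 512))))
        assert res.ccfd_pct == 100.0

    @pytest.mark.parametrize("frac", [0.02, 0.05, 0.10, 0.20])
    def test_recovery_against_generator_truth(self, frac):
        img, truth = generate_cc_enface(AngioParams(target_fd_fraction=frac, seed=31))
        res = compute_ccfd(_enface(img))
        assert abs(res.ccfd_pct - 100.0 * truth.fd_fraction) <= 1.0

    def test_monotone_in_multiplier_and_sigma(self):
        img, _ = generate_cc_enface(AngioParams(
            target_fd_fraction=0.10, noise_sd=20.0, seed=8))
        ef = _enface(img)
        vals = [compute_ccfd(ef, FdThresholdSpec(multiplier=m)).ccfd_pct
                for m in (0.5, 1.0, 1.5, 2.0, 3.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        vals = [compute_ccfd(ef, FdThresholdSpec(sigma_ref=s)).ccfd_pct
                for s in (10.0, 20.0, 30.0, 50.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_roi_pixel_count_matches_circle_area(self):
        res = compute_ccfd(_enface(np.zeros((512, 512))))
        r_px = 2.5e3 / (2 * 5.86)
        assert res.n_roi_px == pytest.approx(np.pi * r_px**2, rel=0.01)

    def test_magnification_shrinks_circle_pixel_count(self):
        img = np.zeros((512, 512))
        n_ref = compute_ccfd(_enface(img), al_mm=24.385).n_roi_px
        n_long = compute_ccfd(_enface(img), al_mm=27.0).n_roi_px
        assert n_long < n_ref

    def test_circle_out_of_field_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            compute_ccfd(_enface(np.zeros((128, 128))))


class TestProjectCcSlab:
    def test_uniform_volume(self):
        vol = np.full((30, 6, 6), 7.0)
        bm = np.full((6, 6), 4, dtype=int)
        out = project_cc_slab(vol, bm, SlabSpec(thickness_um=20), axial_um_per_px=2.0)
        assert np.allclose(out.image, 7.0)

    def test_slab_isolates_bright_layer(self):
        vol = np.full((40, 5, 5), 10.0)
        bm = np.full((5, 5), 6, dtype=int)
        vol[6:16] = 200.0  # 20 µm at 2 µm/px below BM
        out = project_cc_slab(vol, bm, SlabSpec(thickness_um=20), axial_um_per_px=2.0)
        assert np.allclose(out.image, 200.0)

    def test_doubled_thickness_averages_two_layers(self):
        vol = np.full((40, 5, 5), 10.0)
        bm = np.full((5, 5), 5, dtype=int)
        vol[5:15] = 200.0
        out = project_cc_slab(vol, bm, SlabSpec(thickness_um=40), axial_um_per_px=2.0)
        assert np.allclose(out.image, 105.0)  # mean of 200 and 10

    def test_slab_exiting_volume_names_coordinates(self):
        vol = np.zeros((30, 4, 4))
        bm = np.full((4, 4), 2, dtype=int)
        bm[3, 1] = 25  # slab [25, 35) exceeds depth 30 only here
        with pytest.raises(ValueError, match=r"\(3, 1\)"):
            project_cc_slab(vol, bm, SlabSpec(thickness_um=20), axial_um_per_px=2.0)
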