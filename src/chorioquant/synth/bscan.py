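"""Synthetic structural B-scans of the choroid with known vascular ground truth.

Each scene is a speckled grayscale cross-section containing a choroid band
(bright stroma) pierced by dark elliptical vessel lumens.  The generator
records, before any noise is applied, the exact lumen mask, the boundary
curves, and the pixel-counted luminal/stromal/total areas, so downstream
binarization and area measurement can be scored against a known truth.

The speckle model is first-order: multiplicative gamma noise of unit mean,
a standard surrogate for fully-developed OCT speckle after frame averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SceneParams", "SceneTruth", "generate_bscan_scene"]

_MAX_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic B-scan scene.

    Defaults emulate a 12-mm radial line scan sampled by ~2048 A-scans
    (5.86 µm lateral spacing) with a ~270 µm thick submacular choroid and a
    luminal fraction in the physiological low-60s percent range.
    """

    image_width_px: int = 1280
    image_height_px: int = 256
    lateral_um_per_px: float = 5.86
    axial_um_per_px: float = 3.9
    choroid_thickness_um: float = 270.0
    thickness_variation: float = 0.08  # smooth lateral modulation, fraction of thickness
    target_lumen_fraction: float = 0.62
    vessel_radius_range_um: tuple[float, float] = (15.0, 70.0)
    stroma_mean: float = 200.0
    lumen_mean: float = 40.0
    retina_mean: float = 150.0
    sclera_mean: float = 90.0
    upper_boundary_row: int = 90
    speckle_shape: float = 4.0
    roi_width_mm: float = 6.0  # truth areas are reported over this foveal ROI
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_lumen_fraction <= 1.0:
            raise ValueError("target_lumen_fraction must lie in [0, 1]")
        if self.stroma_mean <= self.lumen_mean:
            raise ValueError("stroma_mean must exceed lumen_mean")
        for name in ("image_width_px", "image_height_px", "lateral_um_per_px",
                     "axial_um_per_px", "choroid_thickness_um", "speckle_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        rmin, rmax = self.vessel_radius_range_um
        if not 0 < rmin <= rmax:
            raise ValueError("vessel_radius_range_um must satisfy 0 < rmin <= rmax")


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene, computed before noise by pixel counting.

    Areas are in µm² at the nominal pixel scale; ``true_CVI`` in percent;
    ``true_SFCT`` in µm.  ``true_TCA == true_LA + true_SA`` holds exactly
    because lumen and stroma partition the band's pixels.
    """

    upper_boundary_px: np.ndarray
    lower_boundary_px: np.ndarray
    lumen_mask: np.ndarray
    fovea_col: int
    true_LA: float
    true_SA: float
    true_TCA: float
    true_CVI: float
    true_SFCT: float
    lumen_fraction: float = field(default=0.0)

    def to_json_dict(self) -> dict:
        return {
            "upper_boundary_px": self.upper_boundary_px.astype(int).tolist(),
            "lower_boundary_px": self.lower_boundary_px.astype(int).tolist(),
            "fovea_col": int(self.fovea_col),
            "true_LA_um2": self.true_LA,
            "true_SA_um2": self.true_SA,
            "true_TCA_um2": self.true_TCA,
            "true_CVI_pct": self.true_CVI,
            "true_SFCT_um": self.true_SFCT,
            "lumen_fraction": self.lumen_fraction,
        }


def _band_mask(upper: np.ndarray, lower: np.ndarray, height: int) -> np.ndarray:
    rows = np.arange(height)[:, None]
    return (rows >= upper[None, :]) & (rows < lower[None, :])


def _stamp_ellipse(mask: np.ndarray, cy: float, cx: float, ry: float, rx: float) -> None:
    h, w = mask.shape
    y0, y1 = max(0, int(cy - ry) - 1), min(h, int(cy + ry) + 2)
    x0, x1 = max(0, int(cx - rx) - 1), min(w, int(cx + rx) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    mask[y0:y1, x0:x1] |= inside


def generate_bscan_scene(params: SceneParams) -> tuple[np.ndarray, SceneTruth]:
    """Render one synthetic B-scan and its ground truth.

    Vessel lumens are axis-aligned ellipses (random eccentricity up to 2,
    area preserved) placed by rejection sampling until the realized luminal
    pixel fraction of the choroid band is within ±0.05 of
    ``target_lumen_fraction``.  Overlapping lumens are counted once.  The
    rendered image is the noise-free scene times unit-mean gamma speckle,
    quantized to 8 bits; the truth is computed pre-noise.

    Returns
    -------
    (image, truth)
        ``image`` is a uint8 array of shape (height, width); ``truth`` a
        :class:`SceneTruth`.

    Raises
    ------
    ValueError
        If the target fraction cannot be realized with the given vessel
        radius range within the bounded number of placement attempts.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_height_px, p.image_width_px
    fovea_col = w // 2

    # Smooth boundary curves: gently undulating upper boundary, laterally
    # modulated thickness profile.
    x = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    upper = (p.upper_boundary_row
             + 4.0 * np.sin(2 * np.pi * x / w + phase)).round().astype(int)
    thick_px = p.choroid_thickness_um / p.axial_um_per_px
    profile = 1.0 + p.thickness_variation * np.cos(2 * np.pi * 1.3 * x / w + rng.uniform(0, 2 * np.pi))
    lower = (upper + np.maximum(2, (thick_px * profile).round())).astype(int)
    if lower.max() >= h - 2:
        raise ValueError("choroid band does not fit in the image; increase image_height_px")

    band = _band_mask(upper, lower, h)

    # Truth (and the target fraction) are evaluated over the same half-open
    # submacular ROI the quantification stage measures.
    w_roi = round(p.roi_width_mm * 1000.0 / 2.0 / p.lateral_um_per_px)
    c0, c1 = fovea_col - w_roi, fovea_col + w_roi
    if c0 < 0 or c1 > w:
        raise ValueError(
            f"{p.roi_width_mm}-mm ROI [{c0}, {c1}) exceeds the image width {w}"
        )
    roi_band = band.copy()
    roi_band[:, :c0] = False
    roi_band[:, c1:] = False
    n_band = int(roi_band.sum())

    # Lumen placement by rejection sampling against the target fraction.
    rmin, rmax = p.vessel_radius_range_um
    rmin_px_area = np.pi * (rmin / p.lateral_um_per_px) * (rmin / p.axial_um_per_px)
    if p.target_lumen_fraction > 0 and rmin_px_area / n_band > p.target_lumen_fraction + 0.05:
        raise ValueError(
            "target_lumen_fraction unreachable: the smallest allowed vessel "
            f"already covers {rmin_px_area / n_band:.3f} of the band"
        )

    lumen = np.zeros((h, w), dtype=bool)
    target = p.target_lumen_fraction
    if target > 0:
        max_ellipses = int(3 * target * n_band / max(rmin_px_area, 1.0)) + 10
        ok = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            lumen[:] = False
            frac = 0.0
            for _ in range(max_ellipses):
                r_um = rng.uniform(rmin, rmax)
                ecc = rng.uniform(1.0, 2.0)
                rx = r_um * np.sqrt(ecc) / p.lateral_um_per_px
                ry = r_um / np.sqrt(ecc) / p.axial_um_per_px
                cx = rng.uniform(0, w)
                cy = rng.uniform(upper[min(int(cx), w - 1)], lower[min(int(cx), w - 1)])
                _stamp_ellipse(lumen, cy, cx, ry, rx)
                frac = (lumen & roi_band).sum() / n_band
                if frac >= target:
                    break
            if target <= frac <= target + 0.05:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not realize lumen fraction {target} within "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts (last fraction {frac:.3f})"
            )
    lumen &= band
    roi_lumen = lumen & roi_band
    realized = (roi_lumen.sum() / n_band) if n_band else 0.0

    # Noise-free render: smooth background, band at stroma level, lumens dark.
    img = np.empty((h, w), dtype=float)
    rows = np.arange(h)[:, None]
    img[:] = p.retina_mean
    img[rows >= lower[None, :]] = p.sclera_mean
    img[band] = p.stroma_mean
    img[lumen] = p.lumen_mean
    # gentle lateral illumination ramp
    img *= 1.0 + 0.03 * np.cos(2 * np.pi * x / w)[None, :]

    speckle = rng.gamma(p.speckle_shape, 1.0 / p.speckle_shape, size=img.shape)
    noisy = np.clip(img * speckle, 0, 255).round().astype(np.uint8)

    px_area = p.lateral_um_per_px * p.axial_um_per_px
    la = float(roi_lumen.sum()) * px_area
    sa = float((roi_band & ~lumen).sum()) * px_area
    tca = la + sa
    truth = SceneTruth(
        upper_boundary_px=upper,
        lower_boundary_px=lower,
        lumen_mask=lumen,
        fovea_col=fovea_col,
        true_LA=la,
        true_SA=sa,
        true_TCA=tca,
        true_CVI=(100.0 * la / tca) if tca > 0 else 0.0,
        true_SFCT=float(lower[fovea_col] - upper[fovea_col]) * p.axial_um_per_px,
        lumen_fraction=float(realized),
    )
    return noisy, truth
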