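"""Synthetic en-face choriocapillaris angiograms with known flow-deficit truth.

An angiogram is a perfused texture (bright, noisy) with inserted dark
deficit blobs whose union is recorded as the truth mask.  Optional artifacts
mimic two nuisances of real OCTA slabs: a multiplicative *shadow* (signal
attenuation under a floater or pupil vignetting, recorded as a shadow map)
and bright *projection* stripes where superficial retinal vessels cast
decorrelation tails onto the slab (recorded as a projection mask).  A
co-registered inner-retina reference image carrying the same shadow dip and
vessel stripes is rendered alongside, as compensation algorithms require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AngioParams", "AngioTruth", "generate_cc_enface"]

_MAX_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class AngioParams:
    """Parameters of one synthetic en-face angiogram.

    Defaults emulate a 3 mm × 3 mm scan rendered at 512 px (5.86 µm/px)
    with a physiological deficit fraction near 8%.
    """

    image_size_px: int = 512
    lateral_um_per_px: float = 5.86
    target_fd_fraction: float = 0.08
    deficit_blob_radius_um: tuple[float, float] = (15.0, 60.0)
    perfused_mean: float = 180.0
    deficit_mean: float = 5.0
    noise_sd: float = 5.0
    shadow_attenuation: float = 1.0
    shadow_radius_um: float = 400.0
    projection_vessel_width_um: float = 0.0
    n_projection_vessels: int = 3
    eval_circle_diameter_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perfused_mean <= self.deficit_mean:
            raise ValueError("perfused_mean must exceed deficit_mean")
        if not 0.0 <= self.target_fd_fraction <= 1.0:
            raise ValueError("target_fd_fraction must lie in [0, 1]")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise ValueError("shadow_attenuation must lie in [0, 1]")
        if self.image_size_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValueError("image size and pixel spacing must be positive")
        circle_px = self.eval_circle_diameter_mm * 1000.0 / self.lateral_um_per_px
        if circle_px > self.image_size_px:
            raise ValueError(
                f"evaluation circle ({circle_px:.0f} px) exceeds the field "
                f"({self.image_size_px} px)"
            )


@dataclass
class AngioTruth:
    """Ground truth of a synthetic angiogram.

    ``clean_image`` is the artifact-free render (uint8); ``fd_fraction`` the
    deficit-mask fraction inside the central evaluation circle.
    """

    deficit_mask: np.ndarray
    shadow_map: np.ndarray
    projection_mask: np.ndarray
    clean_image: np.ndarray
    reference_image: np.ndarray
    fd_fraction: float
    fovea_center: tuple[int, int]

    def to_json_dict(self) -> dict:
        return {
            "fd_fraction": self.fd_fraction,
            "fovea_center": list(self.fovea_center),
            "n_deficit_px": int(self.deficit_mask.sum()),
            "n_projection_px": int(self.projection_mask.sum()),
        }


def _disk(mask: np.ndarray, cy: float, cx: float, r: float) -> None:
    n = mask.shape[0]
    y0, y1 = max(0, int(cy - r) - 1), min(n, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(n, int(cx + r) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_cc_enface(params: AngioParams) -> tuple[np.ndarray, AngioTruth]:
    """Render one synthetic choriocapillaris en-face image and its truth.

    Deficit blobs are disks placed by rejection sampling until the realized
    deficit fraction *inside the central evaluation circle* is within ±0.02
    of ``target_fd_fraction``.  The returned image carries the artifacts;
    the truth additionally stores the artifact-free render so compensation
    can be scored against it.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.image_size_px
    center = (n // 2, n // 2)

    yy, xx = np.mgrid[0:n, 0:n]
    r_circle_px = p.eval_circle_diameter_mm * 1000.0 / (2.0 * p.lateral_um_per_px)
    in_circle = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_circle_px**2
    n_circle = int(in_circle.sum())

    rmin, rmax = p.deficit_blob_radius_um
    rmin_px = rmin / p.lateral_um_per_px
    rmax_px = rmax / p.lateral_um_per_px

    deficit = np.zeros((n, n), dtype=bool)
    if p.target_fd_fraction > 0:
        min_blob_frac = np.pi * rmin_px**2 / n_circle
        if min_blob_frac > p.target_fd_fraction + 0.02:
            raise ValueError("target_fd_fraction unreachable with the given blob radii")
        max_blobs = int(3 * p.target_fd_fraction * n_circle / max(np.pi * rmin_px**2, 1.0)) + 10
        ok = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            deficit[:] = False
            frac = 0.0
            for _ in range(max_blobs):
                r = rng.uniform(rmin_px, rmax_px)
                cy = rng.uniform(0, n)
                cx = rng.uniform(0, n)
                _disk(deficit, cy, cx, r)
                frac = (deficit & in_circle).sum() / n_circle
                if frac >= p.target_fd_fraction:
                    break
            if p.target_fd_fraction <= frac <= p.target_fd_fraction + 0.02:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not realize deficit fraction {p.target_fd_fraction} "
                f"within {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    fd_frac = float((deficit & in_circle).sum() / n_circle)

    base = np.full((n, n), p.perfused_mean, dtype=float)
    base[deficit] = p.deficit_mean
    if p.noise_sd > 0:
        base += rng.normal(0.0, p.noise_sd, size=base.shape)
    clean = np.clip(base, 0, 255).round().astype(np.uint8)

    # Shadow: a disk region of multiplicative attenuation, offset from center.
    shadow_map = np.ones((n, n), dtype=float)
    r_sh = p.shadow_radius_um / p.lateral_um_per_px
    sh_cy = center[0] + rng.uniform(-0.15, 0.15) * n
    sh_cx = center[1] + rng.uniform(-0.15, 0.15) * n
    shadow_region = (yy - sh_cy) ** 2 + (xx - sh_cx) ** 2 <= r_sh**2
    shadow_map[shadow_region] = p.shadow_attenuation

    # Projection stripes: near-vertical bright vessel tails.
    projection = np.zeros((n, n), dtype=bool)
    if p.projection_vessel_width_um > 0:
        half_w = max(1, round(p.projection_vessel_width_um / (2 * p.lateral_um_per_px)))
        for _ in range(p.n_projection_vessels):
            x0 = rng.integers(half_w, n - half_w)
            projection[:, x0 - half_w : x0 + half_w + 1] = True

    with_artifacts = base * shadow_map
    with_artifacts[projection] = 250.0
    image = np.clip(with_artifacts, 0, 255).round().astype(np.uint8)

    # Inner-retina reference: flat vascular bed sharing the shadow and vessels.
    ref = np.full((n, n), 128.0)
    ref *= shadow_map
    ref[projection] = 250.0
    ref = np.clip(ref + rng.normal(0, 2.0, size=ref.shape), 1, 255).round().astype(np.uint8)

    truth = AngioTruth(
        deficit_mask=deficit,
        shadow_map=shadow_map,
        projection_mask=projection,
        clean_image=clean,
        reference_image=ref,
        fd_fraction=fd_frac,
        fovea_center=center,
    )
    return image, truth
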