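"""Scan geometry and ocular magnification correction.

OCT devices assume a reference eye when converting scan angles to lateral
distances on the fundus.  In eyes longer or shorter than that reference the
true lateral scale differs, which biases any area measured in "device
millimetres".  The abbreviated axial-length scaling of Bennett corrects the
lateral scale by the ratio of the distances from the eye's second nodal
point to the retina, approximated as (AL - 1.82) mm.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Second-nodal-point offset of the reduced eye, mm (Bennett's abbreviation).
NODAL_POINT_OFFSET_MM = 1.82

#: Axial length of the device-assumed reference eye, mm.
DEFAULT_REFERENCE_AL_MM = 24.385


def magnification_scale(al_mm: float, reference_al_mm: float = DEFAULT_REFERENCE_AL_MM) -> float:
    """Lateral magnification factor of an eye relative to the reference eye.

    The corrected lateral pixel spacing is ``nominal_spacing * scale``.  The
    factor is strictly increasing in axial length: a longer eye spreads the
    same scan angle over more retina, so each pixel covers more micrometres.

    Parameters
    ----------
    al_mm : float
        Subject's axial length in mm.  Must lie in the physiological
        range (15, 40).
    reference_al_mm : float
        Axial length the device's nominal scale assumes, mm.

    Returns
    -------
    float
        ``(al_mm - 1.82) / (reference_al_mm - 1.82)``, dimensionless.
    """
    for name, val in (("al_mm", al_mm), ("reference_al_mm", reference_al_mm)):
        if not 15.0 < val < 40.0:
            raise ValueError(f"{name}={val!r} outside the physiological range (15, 40) mm")
    return (al_mm - NODAL_POINT_OFFSET_MM) / (reference_al_mm - NODAL_POINT_OFFSET_MM)


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel scales and landmarks of one structural B-scan.

    Attributes
    ----------
    lateral_um_per_px : float
        Nominal (device) lateral spacing, µm per pixel.
    axial_um_per_px : float
        Axial (depth) spacing, µm per pixel; taken as AL-independent.
    fovea_col : int
        Image column under the fovea.
    al_mm : float
        Subject's axial length, mm.
    reference_al_mm : float
        Device-assumed axial length, mm.
    nominal_scan_length_mm : float | None
        Advertised scan length, mm (informational).
    """

    lateral_um_per_px: float
    axial_um_per_px: float
    fovea_col: int
    al_mm: float = DEFAULT_REFERENCE_AL_MM
    reference_al_mm: float = DEFAULT_REFERENCE_AL_MM
    nominal_scan_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.lateral_um_per_px <= 0 or self.axial_um_per_px <= 0:
            raise ValueError("pixel spacings must be positive")
        if not 15.0 < self.al_mm < 40.0:
            raise ValueError(f"al_mm={self.al_mm} outside (15, 40) mm")

    @property
    def scale(self) -> float:
        """Magnification factor relative to the reference eye."""
        return magnification_scale(self.al_mm, self.reference_al_mm)

    @property
    def corrected_lateral_um_per_px(self) -> float:
        """Lateral spacing after axial-length magnification correction, µm."""
        return self.lateral_um_per_px * self.scale
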