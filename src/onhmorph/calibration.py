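"""Pixel-to-distance calibration for ONH OCT volumes.

Transverse (en-face) scaling converts the scanner's field angle to
millimetres on the retina using Bennett's abbreviated model-eye scaling,

    q = 0.01306 * (AEL - 1.82)   [mm per degree of visual angle],

where AEL is the axial eye length in mm, so a scan of ``scan_angle_deg``
degrees imaged onto ``n_pixels_transverse`` pixels has a transverse pitch
of ``q * scan_angle_deg / n_pixels_transverse`` mm/pixel.

Axial scaling divides the optical path length per pixel by the tissue
group refractive index (default 1.38 for retinal tissue).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Bennett abbreviated scaling constant, mm per degree per mm of (AEL - 1.82).
BENNETT_FACTOR = 0.01306
#: Nodal-point offset of the reduced eye, mm.
BENNETT_OFFSET_MM = 1.82
#: Default group refractive index of retinal tissue.
DEFAULT_TISSUE_INDEX = 1.38


class CalibrationError(ValueError):
    """Raised for nonphysical calibration parameters."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Scanner geometry and ocular biometry needed for calibration.

    Parameters
    ----------
    scan_angle_deg : float
        Transverse field of view in degrees (< 90).
    n_pixels_transverse : int
        Number of transverse pixels across the field.
    axial_pixel_optical_um : float
        Optical path length per axial pixel, micrometres.
    axial_eye_length_mm : float
        Axial eye length, millimetres (must exceed the 1.82 mm nodal offset).
    tissue_refractive_index : float
        Group refractive index used for the axial correction (>= 1).
    """

    scan_angle_deg: float = 20.0
    n_pixels_transverse: int = 512
    axial_pixel_optical_um: float = 2.76
    axial_eye_length_mm: float = 23.69
    tissue_refractive_index: float = DEFAULT_TISSUE_INDEX

    def __post_init__(self) -> None:
        if not (0.0 < self.scan_angle_deg < 90.0):
            raise CalibrationError("scan_angle_deg must be in (0, 90)")
        if self.n_pixels_transverse <= 0:
            raise CalibrationError("n_pixels_transverse must be positive")
        if self.axial_pixel_optical_um <= 0:
            raise CalibrationError("axial_pixel_optical_um must be positive")
        if self.axial_eye_length_mm <= BENNETT_OFFSET_MM:
            raise CalibrationError(
                f"axial_eye_length_mm must exceed {BENNETT_OFFSET_MM} mm "
                "(nonphysical eye)"
            )
        if self.tissue_refractive_index < 1.0:
            raise CalibrationError("tissue_refractive_index must be >= 1")


def transverse_scale(spec: CalibrationSpec) -> float:
    """Transverse pitch in mm/pixel via Bennett's abbreviated scaling."""
    q = BENNETT_FACTOR * (spec.axial_eye_length_mm - BENNETT_OFFSET_MM)
    return q * spec.scan_angle_deg / spec.n_pixels_transverse


def axial_scale(spec: CalibrationSpec) -> float:
    """Axial pitch in mm/pixel: optical pitch divided by the tissue index."""
    return spec.axial_pixel_optical_um / spec.tissue_refractive_index / 1000.0


def pixels_to_mm(px: float, scale_mm_per_px: float) -> float:
    """Convert a pixel count to millimetres."""
    return px * scale_mm_per_px


def mm_to_pixels(mm: float, scale_mm_per_px: float) -> float:
    """Convert millimetres to (fractional) pixels."""
    return mm / scale_mm_per_px
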