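"""Anatomical region conventions for optic-nerve-head sector analysis.

The ONH is divided into eight 45-degree sectors named by anatomical
direction.  The canonical frame is a right eye (OD) viewed en face:
+x temporal, +y superior.  Left eyes (OS) are mirrored nasal-temporal
before labelling so that regions pool anatomically across eyes.
"""

from __future__ import annotations

import numpy as np

#: Canonical region order used throughout (spec order of the sector ring).
REGIONS: tuple[str, ...] = ("S", "SN", "N", "IN", "I", "IT", "T", "ST")

#: Regions for prelamina thickness: the eight sectors plus the centre.
PRELAMINA_REGIONS: tuple[str, ...] = REGIONS + ("centre",)

# En-face polar angle (degrees) of each half-meridian for a right eye.
_OD_ANGLES = {
    "T": 0.0, "ST": 45.0, "S": 90.0, "SN": 135.0,
    "N": 180.0, "IN": 225.0, "I": 270.0, "IT": 315.0,
}


def region_angle(region: str, eye: str = "OD") -> float:
    """En-face angle (radians) of a region's half-meridian.

    For a left eye the nasal-temporal axis is mirrored (theta -> 180 - theta),
    so e.g. 'T' points along -x in image coordinates of an OS scan.
    """
    if region not in _OD_ANGLES:
        raise ValueError(f"unknown region {region!r}")
    a = _OD_ANGLES[region]
    if eye == "OS":
        a = (180.0 - a) % 360.0
    elif eye != "OD":
        raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")
    return np.deg2rad(a)


def angle_index(region: str) -> int:
    """Index k such that the canonical-frame angle is k*45 degrees."""
    return int(round(_OD_ANGLES[region] / 45.0))


def profile_to_angle_order(profile: dict[str, float]) -> np.ndarray:
    """Region->value map to an array ordered by canonical angle (T first)."""
    missing = [r for r in REGIONS if r not in profile]
    if missing:
        raise ValueError(f"profile missing regions {missing}")
    out = np.empty(8)
    for r in REGIONS:
        out[angle_index(r)] = profile[r]
    return out


def trig_interp(values_by_angle: np.ndarray, theta: np.ndarray | float) -> np.ndarray:
    """Trigonometric interpolation of 8 samples at 45-degree spacing.

    ``values_by_angle[k]`` is the sample at angle ``k*45deg``.  Returns the
    unique band-limited (harmonics 0..4) interpolant evaluated at ``theta``
    (radians).  The circular mean of the interpolant equals the arithmetic
    mean of the samples.
    """
    v = np.asarray(values_by_angle, dtype=float)
    if v.shape != (8,):
        raise ValueError("expected 8 samples at 45-degree spacing")
    c = np.fft.rfft(v)
    th = np.asarray(theta, dtype=float)
    out = np.full(th.shape, c[0].real / 8.0)
    for m in (1, 2, 3):
        out = out + (2.0 / 8.0) * (c[m].real * np.cos(m * th) - c[m].imag * np.sin(m * th))
    out = out + (1.0 / 8.0) * c[4].real * np.cos(4 * th)
    return out


def trig_interp_profile(profile: dict[str, float], theta, eye: str = "OD"):
    """Interpolate a region->value profile at canonical-frame angles ``theta``.

    ``theta`` is measured in the canonical (right-eye) frame; callers working
    in OS image coordinates should convert angles with :func:`region_angle`.
    """
    del eye  # profiles are anatomical; angles are canonical-frame already
    return trig_interp(profile_to_angle_order(profile), theta)
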