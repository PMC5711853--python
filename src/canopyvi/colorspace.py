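"""Color-space transforms underlying the RGB vegetation indices.

Device RGB (assumed sRGB-encoded, 8-bit, D65 white point) is mapped into the
three color models used for canopy color analysis:

* **HSI** — hue as an angle over the visible spectrum (0° red, 60° yellow,
  120° green, 180° cyan), saturation as ``1 − min(r,g,b)/I`` with intensity
  ``I = (r+g+b)/3``.  Hue and saturation are computed on the gamma-encoded
  channels, as consumer imaging tools do.
* **CIELab** — lightness L* (0–100) plus the green(−)/red(+) axis a* and the
  blue(−)/yellow(+) axis b*.
* **CIELuv** — lightness L* plus the perceptually uniform chromaticity
  coordinates u* (scales toward red) and v*.

Lab and Luv are computed from gamma-decoded linear RGB through the CIE XYZ
space (D65, 2° observer); no chromatic adaptation beyond D65 is applied.
All functions are vectorized: they accept a single ``(3,)`` pixel or any
``(..., 3)`` array of pixels.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "decode_srgb",
    "rgb_to_hsi",
    "hue_angle",
    "rgb_to_cielab",
    "rgb_to_cieluv",
    "circular_mean_hue",
]


def _normalize(rgb: np.ndarray) -> np.ndarray:
    """Validate an RGB array and return float channels on [0, 1].

    Integer input is treated as 8-bit (0–255); float input is treated as
    already normalized to [0, 1].  Out-of-range channels raise ``ValueError``.
    """
    arr = np.asarray(rgb)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of 3 channels, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("8-bit channels must lie in [0, 255]")
        return arr / 255.0
    arr = arr.astype(float)
    if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
        raise ValueError("float channels must lie in [0, 1]")
    return arr


def decode_srgb(rgb) -> np.ndarray:
    """Decode sRGB-encoded channels to linear RGB on [0, 1].

    Applies the standard piecewise sRGB transfer function; 0 maps to 0 and
    255 (or 1.0) maps to 1.
    """
    c = _normalize(rgb)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def hue_angle(rgb) -> np.ndarray:
    """Hexcone hue angle in degrees on [0, 360); achromatic pixels get 0.

    Hue is scale-invariant, so it is computed on the raw channel values
    (integers stay exact, avoiding rounding drift at window boundaries).
    """
    _normalize(rgb)  # range validation only
    x = np.asarray(rgb, dtype=float)
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    mx = np.max(x, axis=-1)
    mn = np.min(x, axis=-1)
    delta = mx - mn
    safe = np.where(delta > 0, delta, 1.0)
    hue = np.zeros_like(mx)
    rmax = (delta > 0) & (r == mx)
    gmax = (delta > 0) & (g == mx) & ~rmax
    bmax = (delta > 0) & ~rmax & ~gmax
    hue = np.where(rmax, (60.0 * ((g - b) / safe)) % 360.0, hue)
    hue = np.where(gmax, 60.0 * (2.0 + (b - r) / safe), hue)
    hue = np.where(bmax, 60.0 * (4.0 + (r - g) / safe), hue)
    return hue


def rgb_to_hsi(rgb) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert RGB to (hue_deg, saturation, intensity).

    Hue is the hexcone angle on [0, 360); saturation is the HSI variant
    ``1 − min/I`` on [0, 1] (exactly 0 iff r=g=b); intensity is the mean of
    the normalized channels.
    """
    x = _normalize(rgb)
    mn = np.min(x, axis=-1)
    mx = np.max(x, axis=-1)
    intensity = np.mean(x, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(intensity > 0, 1.0 - mn / np.where(intensity > 0, intensity, 1.0), 0.0)
    # r=g=b must give exactly 0 (mean of equal floats is not bit-exact)
    sat = np.where(mx == mn, 0.0, np.clip(sat, 0.0, 1.0))
    return hue_angle(rgb), sat, intensity


def _via_skimage(rgb, converter) -> np.ndarray:
    x = _normalize(rgb)
    flat = x.reshape(1, -1, 3)
    out = converter(flat).reshape(x.shape)
    # the sRGB->XYZ matrix is rounded, leaving ~1e-3 residual chroma on the
    # neutral axis; achromatic input is neutral by definition, so collapse it
    achromatic = (x[..., 0] == x[..., 1]) & (x[..., 1] == x[..., 2])
    out[..., 1] = np.where(achromatic, 0.0, out[..., 1])
    out[..., 2] = np.where(achromatic, 0.0, out[..., 2])
    return out


def rgb_to_cielab(rgb) -> np.ndarray:
    """Convert sRGB to CIELab (D65/2°); returns an ``(..., 3)`` array (L*, a*, b*)."""
    return _via_skimage(rgb, _skcolor.rgb2lab)


def rgb_to_cieluv(rgb) -> np.ndarray:
    """Convert sRGB to CIELuv (D65/2°); returns an ``(..., 3)`` array (L*, u*, v*)."""
    return _via_skimage(rgb, _skcolor.rgb2luv)


def circular_mean_hue(hues_deg, weights=None) -> float:
    """Circular (vector) mean of hue angles, in degrees on [0, 360).

    Angular quantities cannot be averaged linearly: the mean of 350° and 10°
    is 0°, not 180°.  Each hue is mapped to a unit vector, vectors are
    averaged with the given nonnegative weights, and the resultant angle is
    returned.  A zero resultant (perfectly balanced input) returns 0.0 by
    convention.

    Raises ``ValueError`` on empty input or zero total weight.
    """
    h = np.asarray(hues_deg, dtype=float).ravel()
    if h.size == 0:
        raise ValueError("circular mean of an empty hue set")
    if weights is None:
        w = np.ones_like(h)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != h.shape:
            raise ValueError("weights must match hues in length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total hue weight is zero")
    rad = np.deg2rad(h)
    s = float(np.sum(w * np.sin(rad)) / total)
    c = float(np.sum(w * np.cos(rad)) / total)
    if abs(s) < 1e-12 and abs(c) < 1e-12:
        return 0.0
    ang = float(np.rad2deg(np.arctan2(s, c))) % 360.0
    return 0.0 if ang >= 360.0 - 1e-9 else ang
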