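"""Plot-level RGB vegetation indices.

A plot image is reduced to ten color indices: the mean Intensity, circular
mean Hue, mean Saturation, mean Lightness (CIELab L*), mean a*, b*, u*, v*,
and the two canopy-cover fractions

* **GA** (Green Area) — fraction of pixels with hue in [60°, 180°]
  (yellow through bluish green), a proxy for green canopy cover;
* **GGA** (Greener Area) — fraction with hue in [80°, 180°], excluding
  yellowish-green tones, hence always ≤ GA.

Hue-window bounds are inclusive; achromatic pixels (r=g=b, where hue is
undefined) are never counted green and carry zero weight in the hue mean.
No saturation or lightness floor is applied before hue classification.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import colorspace

__all__ = ["ColorSummary", "summarize_rgb_plot", "green_area", "greener_area",
           "GA_HUE_WINDOW", "GGA_HUE_WINDOW"]

GA_HUE_WINDOW = (60.0, 180.0)
GGA_HUE_WINDOW = (80.0, 180.0)


@dataclass(frozen=True)
class ColorSummary:
    """Per-plot RGB index vector."""

    intensity: float      # mean of normalized channels, 0-1
    hue_deg: float        # circular mean hue of chromatic pixels, 0-360
    saturation: float     # mean HSI saturation, 0-1
    lightness: float      # mean CIELab L*, 0-100
    a_star: float
    b_star: float
    u_star: float
    v_star: float
    ga: float             # green area fraction, 0-1
    gga: float            # greener area fraction, 0 <= gga <= ga
    n_pixels: int

    def __post_init__(self):
        if self.n_pixels <= 0:
            raise ValueError("ColorSummary requires n_pixels > 0")
        if not (0.0 <= self.gga <= self.ga <= 1.0):
            raise ValueError("requires 0 <= gga <= ga <= 1")

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + f.name: getattr(self, f.name) for f in fields(self)}


def _flat_pixels(image, mask):
    """Return an (N, 3) pixel array restricted to the mask."""
    pixels = getattr(image, "pixels", image)
    arr = np.asarray(pixels)
    if arr.ndim == 2 and arr.shape[-1] == 3:
        flat = arr
    elif arr.ndim >= 2 and arr.shape[-1] == 3:
        flat = arr.reshape(-1, 3)
    else:
        raise ValueError(f"expected (..., 3) pixel array, got shape {arr.shape}")
    if flat.shape[0] == 0:
        raise ValueError("empty image")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape[0] != flat.shape[0]:
            raise ValueError("mask shape does not match image")
        if not m.any():
            raise ValueError("mask selects no pixels")
        flat = flat[m]
    return flat


def _hue_fraction(flat: np.ndarray, window: tuple[float, float]) -> float:
    hue, sat, _ = colorspace.rgb_to_hsi(flat)
    chromatic = sat > 0
    lo, hi = window
    inside = chromatic & (hue >= lo) & (hue <= hi)
    return float(inside.sum()) / flat.shape[0]


def green_area(image, mask=None) -> float:
    """Fraction of (masked) pixels with hue in the GA window [60°, 180°]."""
    return _hue_fraction(_flat_pixels(image, mask), GA_HUE_WINDOW)


def greener_area(image, mask=None) -> float:
    """Fraction of (masked) pixels with hue in the GGA window [80°, 180°]."""
    return _hue_fraction(_flat_pixels(image, mask), GGA_HUE_WINDOW)


def summarize_rgb_plot(image, mask=None) -> ColorSummary:
    """Reduce one plot image to its ten RGB indices.

    All means are over masked pixels only.  Hue is a circular mean restricted
    to chromatic pixels (a fully achromatic image reports hue 0).  Lightness
    is the CIELab L* mean; Intensity is the mean normalized channel value.
    """
    flat = _flat_pixels(image, mask)
    hue, sat, inten = colorspace.rgb_to_hsi(flat)
    lab = colorspace.rgb_to_cielab(flat)
    luv = colorspace.rgb_to_cieluv(flat)
    chromatic = sat > 0
    lo_ga, hi_ga = GA_HUE_WINDOW
    lo_gga, hi_gga = GGA_HUE_WINDOW
    n = flat.shape[0]
    ga = float((chromatic & (hue >= lo_ga) & (hue <= hi_ga)).sum()) / n
    gga = float((chromatic & (hue >= lo_gga) & (hue <= hi_gga)).sum()) / n
    if chromatic.any():
        hue_mean = colorspace.circular_mean_hue(hue, weights=chromatic.astype(float))
    else:
        hue_mean = 0.0
    return ColorSummary(
        intensity=float(inten.mean()),
        hue_deg=hue_mean,
        saturation=float(sat.mean()),
        lightness=float(lab[:, 0].mean()),
        a_star=float(lab[:, 1].mean()),
        b_star=float(lab[:, 2].mean()),
        u_star=float(luv[:, 1].mean()),
        v_star=float(luv[:, 2].mean()),
        ga=ga,
        gga=gga,
        n_pixels=n,
    )
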