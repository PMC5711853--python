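"""Independent reference implementations used as test oracles.

Everything here is coded directly from the standard published definitions
(scalar, loop-based, no imports from the package under test) so that
agreement with the package is a genuine dual-route check:

* scalar sRGB → XYZ (D65/2°) → CIELab / CIELuv chain;
* scalar hexcone hue + HSI saturation;
* a naive per-pixel GA/GGA counting loop;
* literal re-typings of the printed spectral-index formula strings.
"""

import math

# classic sRGB -> XYZ matrix (linear RGB, D65) and the D65 2-degree white
_XYZ_M = (
    (0.412453, 0.357580, 0.180423),
    (0.212671, 0.715160, 0.072169),
    (0.019334, 0.119193, 0.950227),
)
_WHITE = (0.95047, 1.0, 1.08883)


def srgb_decode_scalar(c8: float) -> float:
    c = c8 / 255.0
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def rgb_to_xyz(r8, g8, b8):
    rl, gl, bl = (srgb_decode_scalar(v) for v in (r8, g8, b8))
    return tuple(m[0] * rl + m[1] * gl + m[2] * bl for m in _XYZ_M)


def _f_lab(t: float) -> float:
    eps = (6.0 / 29.0) ** 3
    if t > eps:
        return t ** (1.0 / 3.0)
    return t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0


def rgb_to_lab(r8, g8, b8):
    x, y, z = rgb_to_xyz(r8, g8, b8)
    xn, yn, zn = _WHITE
    fx, fy, fz = _f_lab(x / xn), _f_lab(y / yn), _f_lab(z / zn)
    return (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def rgb_to_luv(r8, g8, b8):
    x, y, z = rgb_to_xyz(r8, g8, b8)
    xn, yn, zn = _WHITE
    L = 116.0 * _f_lab(y / yn) - 16.0
    denom = x + 15.0 * y + 3.0 * z
    denom_n = xn + 15.0 * yn + 3.0 * zn
    if denom == 0.0:
        up, vp = 4.0 * xn / denom_n, 9.0 * yn / denom_n
    else:
        up, vp = 4.0 * x / denom, 9.0 * y / denom
    upn, vpn = 4.0 * xn / denom_n, 9.0 * yn / denom_n
    return (L, 13.0 * L * (up - upn), 13.0 * L * (vp - vpn))


def hue_scalar(r8, g8, b8) -> float:
    """Hexcone hue in degrees on [0, 360); 0 for achromatic pixels.

    Computed on raw channel values — hue is scale-invariant and integer
    channel differences divide exactly, so window-boundary hues (60, 80,
    180 deg) are bit-deterministic."""
    mx, mn = max(r8, g8, b8), min(r8, g8, b8)
    delta = mx - mn
    if delta == 0:
        return 0.0
    if r8 == mx:
        return (60.0 * ((g8 - b8) / delta)) % 360.0
    if g8 == mx:
        return 60.0 * (2.0 + (b8 - r8) / delta)
    return 60.0 * (4.0 + (r8 - g8) / delta)


def hsi_scalar(r8, g8, b8):
    i = (r8 + g8 + b8) / (3.0 * 255.0)
    mn = min(r8, g8, b8) / 255.0
    if r8 == g8 == b8:
        s = 0.0
    else:
        s = 1.0 - mn / i
    return hue_scalar(r8, g8, b8), s, i


def count_green_loop(pixels):
    """Naive GA/GGA counts over an (H, W, 3) uint8 array; returns
    (n_ga, n_gga, n_total).  Achromatic pixels are never green."""
    n_ga = n_gga = n_tot = 0
    h, w, _ = pixels.shape
    for yy in range(h):
        for xx in range(w):
            r, g, b = (int(v) for v in pixels[yy, xx])
            n_tot += 1
            if r == g == b:
                continue
            hue = hue_scalar(r, g, b)
            if 60.0 <= hue <= 180.0:
                n_ga += 1
            if 80.0 <= hue <= 180.0:
                n_gga += 1
    return n_ga, n_gga, n_tot


# literal re-typings of the printed index formula strings (B<wl> = b[wl]);
# the TCARI entry is the string as literally parsed
LITERAL_FORMULAS = {
    "ndvi": lambda b, L: (b[840] - b[670]) / (b[840] + b[670]),
    "savi": lambda b, L: (b[840] - b[670]) / (b[840] + b[670] + L) * (1 + L),
    "osavi": lambda b, L: ((1 + 0.16) * (b[780] - b[670])) / ((b[780] + b[670] + 0.16)),
    "rdvi": lambda b, L: (b[840] - b[670]) / ((b[840] + b[670]) ** (1 / 2)),
    "evi": lambda b, L: 2.5 * (b[840] - b[670]) / (b[840] + (6 * b[670]) - (7.5 * b[450]) + 1),
    "pri": lambda b, L: (b[550] - b[570]) / (b[550] + b[570]),
    "mcari": lambda b, L: ((b[700] - b[670]) - 0.2 * (b[700] - b[550])) * b[700] / b[670],
    "tcari": lambda b, L: 3 * (b[700] - b[670]) - 0.2 * (b[700] - b[550]) * (b[700] / b[670]),
    "ari2": lambda b, L: b[840] * (1 / b[550] - 1 / b[700]),
    "cri2": lambda b, L: 1 / b[550] - 1 / b[700],
    "wbi": lambda b, L: (b[840] - b[670]) / (b[840] + b[670]) ** (1 / 2),
}
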