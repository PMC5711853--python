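"""Multispectral vegetation indices from narrow-band reflectance stacks.

The camera model is an 11-band visible/NIR imager with bands centered at
450, 550, 570, 670, 700, 720, 780, 840, 860, 900 and 950 nm.  Twelve indices
are computed, grouped as broadband greenness (NDVI, SAVI, OSAVI, RDVI, EVI),
light-use efficiency (PRI), leaf pigments (MCARI, TCARI, ARI2, CRI2) and
canopy water (WBI), plus the TCARI/OSAVI soil-resistant ratio.

Formulas (B<λ> is reflectance at λ nm, 0-1):

    NDVI  = (B840 − B670) / (B840 + B670)
    SAVI  = (B840 − B670) / (B840 + B670 + L) · (1 + L)
            with soil factor L = 1 (low vegetation), 0.5 (intermediate,
            the default) or 0.25 (high)
    OSAVI = (1 + 0.16) · (B780 − B670) / (B780 + B670 + 0.16)
    RDVI  = (B840 − B670) / √(B840 + B670)
    EVI   = 2.5 · (B840 − B670) / (B840 + 6·B670 − 7.5·B450 + 1)
    PRI   = (B550 − B570) / (B550 + B570)
    MCARI = [(B700 − B670) − 0.2·(B700 − B550)] · B700/B670
    TCARI = 3·[(B700 − B670) − 0.2·(B700 − B550)·(B700/B670)]
    ARI2  = B840 · (1/B550 − 1/B700)
    CRI2  = 1/B550 − 1/B700
    WBI   = (B840 − B670) / √(B840 + B670)

Two fidelity caveats, kept deliberately visible:

* ``tcari`` defaults to the canonical bracketing above, but the source table
  this camera configuration was printed with is parenthesis-ambiguous and
  literally parses as ``3·(B700−B670) − 0.2·(B700−B550)·(B700/B670)``; that
  variant is available via ``form="literal"``.
* ``wbi`` is implemented exactly as printed in the same table, where it has
  the identical algebraic shape as RDVI rather than the canonical 900/970 nm
  water band ratio; the latter is provided separately as
  :func:`water_index_900_970`.

Zero denominators yield NaN (an explicit undefined-value sentinel, never a
silent infinity); summaries record which indices were undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CAMERA_WAVELENGTHS",
    "INDEX_NAMES",
    "BandStack",
    "SpectralSummary",
    "spectral_index",
    "summarize_spectral_plot",
    "water_index_900_970",
    "DEFAULT_SAVI_L",
]

CAMERA_WAVELENGTHS = (450, 550, 570, 670, 700, 720, 780, 840, 860, 900, 950)
DEFAULT_SAVI_L = 0.5


def _div(num, den):
    """Division with NaN where the denominator vanishes."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, num / np.where(den == 0, 1.0, den))
    return out if out.ndim else float(out)


def _sqrt(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.sqrt(x)
    return out if out.ndim else float(out)


def _ndvi(b, L):
    return _div(b[840] - b[670], b[840] + b[670])


def _savi(b, L):
    return _div((b[840] - b[670]) * (1.0 + L), b[840] + b[670] + L)


def _osavi(b, L):
    return _div((1.0 + 0.16) * (b[780] - b[670]), b[780] + b[670] + 0.16)


def _rdvi(b, L):
    return _div(b[840] - b[670], _sqrt(b[840] + b[670]))


def _evi(b, L):
    return _div(2.5 * (b[840] - b[670]), b[840] + 6.0 * b[670] - 7.5 * b[450] + 1.0)


def _pri(b, L):
    return _div(b[550] - b[570], b[550] + b[570])


def _mcari(b, L):
    return ((b[700] - b[670]) - 0.2 * (b[700] - b[550])) * _div(b[700], b[670])


def _tcari_canonical(b, L):
    return 3.0 * ((b[700] - b[670]) - 0.2 * (b[700] - b[550]) * _div(b[700], b[670]))


def _tcari_literal(b, L):
    return 3.0 * (b[700] - b[670]) - 0.2 * (b[700] - b[550]) * _div(b[700], b[670])


def _ari2(b, L):
    return b[840] * (_div(1.0, b[550]) - _div(1.0, b[700]))


def _cri2(b, L):
    return _div(1.0, b[550]) - _div(1.0, b[700])


def _wbi(b, L):
    # as printed: same algebraic shape as RDVI (see module docstring)
    return _div(b[840] - b[670], _sqrt(b[840] + b[670]))


_DEFINITIONS = {
    "ndvi": ((670, 840), _ndvi),
    "savi": ((670, 840), _savi),
    "osavi": ((670, 780), _osavi),
    "rdvi": ((670, 840), _rdvi),
    "evi": ((450, 670, 840), _evi),
    "pri": ((550, 570), _pri),
    "mcari": ((550, 670, 700), _mcari),
    "tcari": ((550, 670, 700), _tcari_canonical),
    "ari2": ((550, 700, 840), _ari2),
    "cri2": ((550, 700), _cri2),
    "wbi": ((670, 840), _wbi),
}

INDEX_NAMES = tuple(_DEFINITIONS) + ("tcari_osavi",)


def water_index_900_970(r900: float, r970: float) -> float:
    """Canonical water band index R900/R970 (not computable from this camera's
    band set, which lacks 970 nm; provided for cross-instrument comparison)."""
    return _div(r900, r970)


def spectral_index(name: str, band_values, L: float = DEFAULT_SAVI_L,
                   form: str = "canonical"):
    """Evaluate one spectral index on a wavelength→reflectance mapping.

    ``band_values`` maps center wavelengths (nm) to reflectances in [0, 1];
    values may be scalars or aligned arrays.  ``L`` is the SAVI soil factor.
    ``form`` selects the TCARI bracketing ("canonical" or "literal").
    Missing bands raise ``KeyError``; zero denominators return NaN.
    """
    key = name.lower()
    if key == "tcari_osavi":
        return _div(spectral_index("tcari", band_values, L, form),
                    spectral_index("osavi", band_values, L, form))
    if key not in _DEFINITIONS:
        raise KeyError(f"unknown spectral index {name!r}; known: {sorted(INDEX_NAMES)}")
    needed, fn = _DEFINITIONS[key]
    missing = [wl for wl in needed if wl not in band_values]
    if missing:
        raise KeyError(f"index {name!r} needs band(s) {missing} nm")
    for wl in needed:
        v = np.asarray(band_values[wl], dtype=float)
        if v.size and (np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0):
            raise ValueError(f"reflectance at {wl} nm outside [0, 1]")
    if key == "tcari" and form == "literal":
        fn = _tcari_literal
    elif form not in ("canonical", "literal"):
        raise ValueError("form must be 'canonical' or 'literal'")
    return fn({wl: np.asarray(band_values[wl], dtype=float) for wl in needed}, L)


@dataclass
class BandStack:
    """Co-registered 2-D reflectance maps keyed by center wavelength (nm)."""

    bands: dict[int, np.ndarray]
    mask: np.ndarray | None = None
    plot_id: str | None = None

    def __post_init__(self):
        if not self.bands:
            raise ValueError("BandStack needs at least one band")
        shapes = set()
        clean = {}
        for wl, arr in self.bands.items():
            wl = int(wl)
            if wl not in CAMERA_WAVELENGTHS:
                raise ValueError(f"unsupported wavelength {wl} nm; camera bands are {CAMERA_WAVELENGTHS}")
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2:
                raise ValueError(f"band {wl} must be a 2-D map")
            if a.size and (a.min() < 0.0 or a.max() > 1.0):
                raise ValueError(f"band {wl} has reflectance outside [0, 1]")
            shapes.add(a.shape)
            clean[wl] = a
        if len(shapes) != 1:
            raise ValueError(f"bands must share one shape, got {sorted(shapes)}")
        self.bands = clean
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != next(iter(shapes)):
                raise ValueError("mask shape does not match bands")
            self.mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.bands))


@dataclass(frozen=True)
class SpectralSummary:
    """Per-plot spectral index vector plus per-band mean reflectances."""

    ndvi: float
    savi: float
    osavi: float
    rdvi: float
    evi: float
    pri: float
    mcari: float
    tcari: float
    tcari_osavi: float
    ari2: float
    cri2: float
    wbi: float
    band_means: dict[int, float]
    savi_L: float
    undefined_indices: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self, prefix: str = "", include_bands: bool = True) -> dict[str, float]:
        d = {prefix + name: getattr(self, name) for name in INDEX_NAMES}
        if include_bands:
            for wl, v in sorted(self.band_means.items()):
                d[f"{prefix}b{wl}"] = v
        return d


def summarize_spectral_plot(stack: BandStack, mode: str = "mean-reflectance",
                            L: float = DEFAULT_SAVI_L,
                            form: str = "canonical") -> SpectralSummary:
    """Reduce a band stack to its spectral index vector.

    ``mode="mean-reflectance"`` (default) applies each formula to the plot's
    mean band reflectances — the plot-level convention.  ``mode="per-pixel"``
    evaluates each index per pixel and averages the finite values, for
    sensitivity analysis.  Both agree exactly on spatially uniform stacks.
    """
    if mode not in ("mean-reflectance", "per-pixel"):
        raise ValueError("mode must be 'mean-reflectance' or 'per-pixel'")
    if stack.mask is not None:
        if not stack.mask.any():
            raise ValueError("mask selects no pixels")
        flat = {wl: arr[stack.mask] for wl, arr in stack.bands.items()}
    else:
        flat = {wl: arr.ravel() for wl, arr in stack.bands.items()}
    band_means = {wl: float(v.mean()) for wl, v in flat.items()}

    values: dict[str, float] = {}
    undefined: list[str] = []
    for name in INDEX_NAMES:
        try:
            if mode == "mean-reflectance":
                val = spectral_index(name, band_means, L, form)
                val = float(val)
            else:
                per_pixel = np.asarray(spectral_index(name, flat, L, form), dtype=float)
                finite = np.isfinite(per_pixel)
                val = float(per_pixel[finite].mean()) if finite.any() else math.nan
        except KeyError:
            val = math.nan
        if math.isnan(val):
            undefined.append(name)
        values[name] = val
    return SpectralSummary(band_means=band_means, savi_L=L,
                           undefined_indices=tuple(undefined), **values)
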