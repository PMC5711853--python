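"""Synthetic canopy scenes and two-treatment field trials.

No image or yield data accompany the study design this package analyses, so
everything downstream is exercised on generated material with the same
statistical structure:

* **Scenes** — maize seedlings rendered as random elliptical blobs (rosette
  scale) over a textured soil background, so that block-mean downsampling
  produces genuine vegetation/soil mixed pixels at canopy boundaries.  The
  realized green-pixel count hits the requested cover fraction exactly (the
  last blob is trimmed pixel-by-pixel), and per-class pixel counts are
  returned as ground truth.  Phosphorus starvation is emulated by two dials:
  *chlorosis* (hue shift of the foliage from green toward yellow, plus a
  flattened red-edge in the reflectance stack) and *purpling* (extra dark
  red-purple foliage, the classic P-deficiency symptom).
* **Band stacks** — an 11-band reflectance image pixel-aligned with the RGB
  scene, built from a two-endmember model (leaf vs soil spectra declared as
  constants below); chlorosis raises red (670 nm) and lowers NIR (840 nm)
  leaf reflectance monotonically.
* **Trials** — 26 genotypes × 2 phosphorus regimes (52 plots).  Grain yield
  is treatment mean + genotype effect + a cover-linked term + residual, with
  treatment means defaulting to 5.64 (unfertilized, NPF) and 7.50 t·ha⁻¹
  (optimal P, OP); leaf traits are drawn from treatment-dependent normal
  models.  The planted cover→yield correlation has a closed form exposed as
  :meth:`TrialDesign.planted_cover_yield_correlation`.

One global seed drives a per-plot seed sequence (seed, plot index), so any
single plot is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

from .plot_io import RgbImage
from .records import PlotRecord
from .spectral_indices import CAMERA_WAVELENGTHS, BandStack

__all__ = [
    "SceneParams", "SceneTruth", "TrialDesign", "TrialPlot",
    "generate_canopy_scene", "generate_trial", "leaf_soil_reflectance",
    "LEAF_SPECTRUM_HEALTHY", "LEAF_SPECTRUM_CHLOROTIC", "SOIL_SPECTRUM",
]

# ---------------------------------------------------------------------------
# endmember spectra (declared constants; reflectance 0-1 per wavelength, nm)
# Healthy leaf: strong chlorophyll absorption at 670 nm, sharp red edge,
# high NIR plateau.  Chlorotic leaf: weaker red absorption, damped red edge,
# lower NIR.  Soil: slowly rising with wavelength, NDVI ~ 0.1.
LEAF_SPECTRUM_HEALTHY = {
    450: 0.04, 550: 0.12, 570: 0.10, 670: 0.04, 700: 0.15, 720: 0.35,
    780: 0.48, 840: 0.50, 860: 0.50, 900: 0.49, 950: 0.46,
}
LEAF_SPECTRUM_CHLOROTIC = {
    450: 0.07, 550: 0.18, 570: 0.17, 670: 0.14, 700: 0.22, 720: 0.33,
    780: 0.40, 840: 0.40, 860: 0.40, 900: 0.39, 950: 0.37,
}
SOIL_SPECTRUM = {
    450: 0.10, 550: 0.16, 570: 0.17, 670: 0.22, 700: 0.23, 720: 0.24,
    780: 0.26, 840: 0.27, 860: 0.27, 900: 0.28, 950: 0.28,
}


def leaf_soil_reflectance(wavelength: int, material: str, chlorosis: float = 0.0) -> float:
    """Endmember reflectance at one camera wavelength.

    ``material`` is ``"leaf"`` or ``"soil"``; for leaves, ``chlorosis`` in
    [0, 1] interpolates linearly from the healthy to the chlorotic spectrum
    (raising 670 nm and lowering the NIR monotonically).
    """
    wl = int(wavelength)
    if wl not in CAMERA_WAVELENGTHS:
        raise ValueError(f"unsupported wavelength {wl} nm; camera bands are {CAMERA_WAVELENGTHS}")
    if not 0.0 <= chlorosis <= 1.0:
        raise ValueError("chlorosis must lie in [0, 1]")
    if material == "soil":
        return SOIL_SPECTRUM[wl]
    if material == "leaf":
        h, c = LEAF_SPECTRUM_HEALTHY[wl], LEAF_SPECTRUM_CHLOROTIC[wl]
        return h + chlorosis * (c - h)
    raise ValueError("material must be 'leaf' or 'soil'")


# ---------------------------------------------------------------------------
# scene generation


@dataclass
class SceneParams:
    """Parameters of one rendered plot scene.

    ``green_fraction`` is the target green canopy cover (realized exactly in
    pixel bookkeeping).  ``chlorosis`` shifts foliage hue toward yellow and
    flattens the red edge; ``purpling`` adds dark red-purple foliage (an
    extra ~25% of the green area at purpling=1) emulating P deficiency.
    ``image_size`` is (width, height); the default 576×384 is a 1/8 linear
    scale of the 4,608×3,072 px reference ground plot.
    """

    green_fraction: float = 0.15
    chlorosis: float = 0.0
    purpling: float = 0.0
    soil_color: tuple[int, int, int] = (122, 88, 58)
    leaf_color_mean: tuple[int, int, int] = (62, 150, 58)
    leaf_color_scatter: float = 0.08
    image_size: tuple[int, int] = (576, 384)
    canopy_blob_radius: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("green_fraction", "chlorosis", "purpling", "leaf_color_scatter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        w, h = self.image_size
        if w < 8 or h < 8:
            raise ValueError("image_size must be at least 8x8")


@dataclass(frozen=True)
class SceneTruth:
    """Ground-truth pixel bookkeeping for a rendered scene."""

    n_pixels: int
    n_green: int
    n_gga: int
    n_purple: int

    @property
    def n_soil(self) -> int:
        return self.n_pixels - self.n_green - self.n_purple

    @property
    def true_green_fraction(self) -> float:
        return self.n_green / self.n_pixels

    @property
    def true_gga_fraction(self) -> float:
        return self.n_gga / self.n_pixels


def _rgb_to_hsv_center(rgb: tuple[int, int, int]) -> tuple[float, float, float]:
    arr = np.asarray(rgb, dtype=float) / 255.0
    hsv = _skcolor.rgb2hsv(arr.reshape(1, 1, 3))[0, 0]
    return float(hsv[0] * 360.0), float(hsv[1]), float(hsv[2])


def _paint_blobs(rng, shape, target, radius, forbidden=None):
    """Boolean mask with exactly ``target`` True pixels from random ellipses.

    The final ellipse is trimmed pixel-by-pixel so the count is exact; if
    blob placement stalls (mask nearly full) the remainder is filled from
    any free pixels.
    """
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    if target <= 0:
        return mask
    avail = np.ones(shape, dtype=bool) if forbidden is None else ~forbidden
    if target > int(avail.sum()):
        raise ValueError("blob target exceeds available pixels")
    count = 0
    stall = 0
    while count < target:
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        ry = max(1.0, radius * rng.lognormal(0.0, 0.35))
        rx = max(1.0, radius * rng.lognormal(0.0, 0.35))
        y0, y1 = max(0, int(cy - ry) - 1), min(H, int(cy + ry) + 2)
        x0, x1 = max(0, int(cx - rx) - 1), min(W, int(cx + rx) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        new = ellipse & avail[y0:y1, x0:x1] & ~mask[y0:y1, x0:x1]
        k = int(new.sum())
        if k == 0:
            stall += 1
            if stall > 500:
                free = np.flatnonzero(avail & ~mask)
                pick = rng.choice(free, size=target - count, replace=False)
                mask.flat[pick] = True
                return mask
            continue
        stall = 0
        if count + k > target:
            need = target - count
            coords = np.flatnonzero(new)
            pick = rng.choice(coords, size=need, replace=False)
            trimmed = np.zeros_like(new)
            trimmed.flat[pick] = True
            mask[y0:y1, x0:x1] |= trimmed
            count = target
        else:
            mask[y0:y1, x0:x1] |= new
            count += k
    return mask


def _smooth_noise(rng, shape, cell: int = 16):
    """Low-frequency noise field in [-1, 1] for soil texture."""
    H, W = shape
    coarse = rng.uniform(-1.0, 1.0, size=(max(2, H // cell + 2), max(2, W // cell + 2)))
    zy = H / coarse.shape[0]
    zx = W / coarse.shape[1]
    fine = ndimage.zoom(coarse, (zy, zx), order=1, grid_mode=True, mode="nearest")
    return fine[:H, :W]


# rendering clamps: keep every class safely inside / outside the GA and GGA
# hue windows after 8-bit quantization (worst-case hue error < ~3 deg at the
# saturation/value floors below)
_GREEN_HUE_CLIP = (64.0, 177.0)
_GGA_EXCLUSION = (77.0, 83.0)   # no green pixel is assigned a hue here
_SOIL_HUE_CLIP = (8.0, 52.0)
_PURPLE_HUE_CENTER = 345.0


def generate_canopy_scene(params: SceneParams, rng=None):
    """Render one plot: returns ``(RgbImage, BandStack, SceneTruth)``.

    The RGB scene and the reflectance stack are pixel-aligned.  Green cover
    is realized exactly (see :class:`SceneTruth`); every green pixel's hue
    lies inside the GA window and outside a guard band around the GGA
    boundary, so hue-threshold indices agree with the bookkeeping.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed & 0x7FFFFFFF]))
    W, H = params.image_size
    N = H * W
    n_green = int(round(params.green_fraction * N))
    radius = params.canopy_blob_radius
    if radius is None:
        radius = max(2.0, round(0.022 * min(H, W)))

    canopy = _paint_blobs(rng, (H, W), n_green, radius)
    n_purple = int(round(params.purpling * 0.25 * n_green))
    n_purple = min(n_purple, N - n_green)
    purple = _paint_blobs(rng, (H, W), n_purple, max(1.5, radius * 0.6), forbidden=canopy)

    # --- HSV composition ------------------------------------------------
    soil_h, soil_s, soil_v = _rgb_to_hsv_center(params.soil_color)
    leaf_h, leaf_s, leaf_v = _rgb_to_hsv_center(params.leaf_color_mean)
    sc = params.leaf_color_scatter
    hue_sd, sv_sd = 100.0 * sc, sc

    hsv = np.empty((H, W, 3), dtype=float)
    texture = _smooth_noise(rng, (H, W))
    hsv[..., 0] = np.clip(rng.normal(soil_h, 6.0, (H, W)), *_SOIL_HUE_CLIP)
    hsv[..., 1] = np.clip(rng.normal(soil_s, 0.08, (H, W)), 0.30, 0.80)
    hsv[..., 2] = np.clip(soil_v * (1.0 + 0.25 * texture) + rng.normal(0, 0.04, (H, W)),
                          0.20, 0.95)

    n_g = int(canopy.sum())
    if n_g:
        center = leaf_h - 45.0 * params.chlorosis
        gh = np.clip(rng.normal(center, hue_sd, n_g), *_GREEN_HUE_CLIP)
        lo, hi = _GGA_EXCLUSION
        mid = 0.5 * (lo + hi)
        gh = np.where((gh > lo) & (gh < hi), np.where(gh < mid, lo, hi), gh)
        hsv[..., 0][canopy] = gh
        hsv[..., 1][canopy] = np.clip(rng.normal(leaf_s, sv_sd, n_g), 0.35, 0.95)
        hsv[..., 2][canopy] = np.clip(rng.normal(leaf_v * (1.0 - 0.1 * params.chlorosis),
                                                 sv_sd, n_g), 0.28, 0.90)
        n_gga = int((gh >= 80.0).sum())
    else:
        n_gga = 0
    n_p = int(purple.sum())
    if n_p:
        hsv[..., 0][purple] = np.clip(rng.normal(_PURPLE_HUE_CENTER, 10.0, n_p),
                                      300.0, 359.9)
        hsv[..., 1][purple] = np.clip(rng.normal(0.45, 0.10, n_p), 0.30, 0.80)
        hsv[..., 2][purple] = np.clip(rng.normal(0.22, 0.05, n_p), 0.10, 0.40)

    rgb = _skcolor.hsv2rgb(np.stack([hsv[..., 0] / 360.0, hsv[..., 1], hsv[..., 2]],
                                    axis=-1))
    pixels = np.rint(rgb * 255.0).astype(np.uint8)
    image = RgbImage(pixels=pixels, platform="ground")

    # --- band stack (two-endmember model, pixel-aligned) ----------------
    chl = params.chlorosis
    chl_purple = min(1.0, chl + 0.6)
    bands: dict[int, np.ndarray] = {}
    noise = 1.0 + 0.02 * rng.standard_normal((H, W))
    soil_shade = 1.0 + 0.10 * texture
    for wl in CAMERA_WAVELENGTHS:
        base = np.full((H, W), leaf_soil_reflectance(wl, "soil") , dtype=float)
        base *= soil_shade
        base[canopy] = leaf_soil_reflectance(wl, "leaf", chl)
        base[purple] = 0.85 * leaf_soil_reflectance(wl, "leaf", chl_purple)
        bands[wl] = np.clip(base * noise, 0.0, 1.0)
    stack = BandStack(bands=bands)

    truth = SceneTruth(n_pixels=N, n_green=n_green, n_gga=n_gga, n_purple=n_p)
    return image, stack, truth


# ---------------------------------------------------------------------------
# trial generation


def _default_trait_models():
    # trait -> (mean NPF, mean OP, sd NPF, sd OP); means follow the study's
    # treatment summaries, sds are the reported standard errors scaled by
    # sqrt(26) back to plot-level spread
    return {
        "leaf_p": (2.06, 4.81, 0.41, 0.56),
        "lcc": (32.01, 46.19, 5.05, 3.98),
        "leaf_n": (3.95, 4.30, 0.20, 0.31),
        "leaf_c": (43.62, 43.03, 0.51, 1.17),
        "d13c": (-11.66, -11.61, 0.15, 0.20),
        "d15n": (-1.32, -1.09, 1.17, 1.53),
    }


@dataclass
class TrialDesign:
    """Design of a synthetic two-treatment phosphorus trial.

    Defaults reproduce the reference trial: 26 genotypes under no-phosphorus
    (NPF) and optimal-phosphorus (OP) regimes — 52 plots — with treatment
    mean yields 5.64 and 7.50 t·ha⁻¹, green cover means 0.08/0.21, and
    stronger chlorosis and purpling in the unfertilized arm.  Yield is
    ``mean_t + genotype effect + cover_yield_slope·(cover − mean cover_t) +
    residual``.
    """

    n_genotypes: int = 26
    treatments: tuple[str, str] = ("NPF", "OP")
    mean_yield: dict = field(default_factory=lambda: {"NPF": 5.64, "OP": 7.50})
    genotype_sd: float = 0.60
    residual_sd: float = 0.35
    cover_yield_slope: float = 25.0
    cover_mean: dict = field(default_factory=lambda: {"NPF": 0.08, "OP": 0.21})
    cover_sd: dict = field(default_factory=lambda: {"NPF": 0.03, "OP": 0.04})
    chlorosis: dict = field(default_factory=lambda: {"NPF": 0.60, "OP": 0.15})
    purpling: dict = field(default_factory=lambda: {"NPF": 0.50, "OP": 0.05})
    trait_models: dict = field(default_factory=_default_trait_models)
    image_size: tuple[int, int] = (576, 384)
    canopy_blob_radius: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if self.genotype_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * len(self.treatments)

    def planted_cover_yield_correlation(self, treatment: str) -> float:
        """Closed-form within-treatment correlation between green cover and
        yield implied by the variance components (ignoring cover clipping)."""
        s = self.cover_yield_slope * self.cover_sd[treatment]
        denom = np.sqrt(s * s + self.genotype_sd ** 2 + self.residual_sd ** 2)
        return 0.0 if denom == 0 else float(s / denom)


class TrialPlot(NamedTuple):
    record: PlotRecord
    rgb: RgbImage
    stack: BandStack
    truth: SceneTruth


def generate_trial(design: TrialDesign) -> list[TrialPlot]:
    """Generate the full trial: one rendered plot per genotype × treatment.

    Reproducible from ``design.seed``; plot *i* uses the seed sequence
    ``(seed, i)`` so individual plots can be regenerated in isolation.
    """
    seed = int(design.seed) & 0x7FFFFFFF
    rng_design = np.random.default_rng(np.random.SeedSequence([seed, 982451653]))
    genotype_effect = rng_design.normal(0.0, design.genotype_sd, design.n_genotypes)
    genotypes = [f"G{i + 1:02d}" for i in range(design.n_genotypes)]

    plots: list[TrialPlot] = []
    idx = 0
    for treatment in design.treatments:
        for gi, genotype in enumerate(genotypes):
            rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
            cover = float(np.clip(rng.normal(design.cover_mean[treatment],
                                             design.cover_sd[treatment]), 0.005, 0.80))
            chl = float(np.clip(rng.normal(design.chlorosis[treatment], 0.08), 0.0, 1.0))
            pur = float(np.clip(rng.normal(design.purpling[treatment], 0.08), 0.0, 1.0))
            gy = (design.mean_yield[treatment]
                  + genotype_effect[gi]
                  + design.cover_yield_slope * (cover - design.cover_mean[treatment])
                  + rng.normal(0.0, design.residual_sd))
            gy = max(0.0, float(gy))
            traits = {}
            for trait, (m_npf, m_op, s_npf, s_op) in design.trait_models.items():
                mean = m_npf if treatment == "NPF" else m_op
                sd = s_npf if treatment == "NPF" else s_op
                traits[trait] = float(rng.normal(mean, sd))
            c_to_n = traits["leaf_c"] / traits["leaf_n"] if traits.get("leaf_n") else None

            params = SceneParams(green_fraction=cover, chlorosis=chl, purpling=pur,
                                 image_size=design.image_size,
                                 canopy_blob_radius=design.canopy_blob_radius,
                                 seed=seed)
            rgb, stack, truth = generate_canopy_scene(params, rng=rng)
            plot_id = f"{treatment}-{genotype}"
            rgb.plot_id = plot_id
            stack.plot_id = plot_id
            record = PlotRecord(
                plot_id=plot_id, genotype=genotype, treatment=treatment,
                grain_yield=gy, c_to_n=c_to_n,
                **traits,
                extra={"true_green_fraction": truth.true_green_fraction,
                       "true_gga_fraction": truth.true_gga_fraction,
                       "chlorosis": chl, "purpling": pur},
            )
            plots.append(TrialPlot(record, rgb, stack, truth))
            idx += 1
    return plots
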