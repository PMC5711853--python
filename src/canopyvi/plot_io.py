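"""Image and table I/O, plot cropping, and aerial-resolution emulation.

Ground plot photographs are high resolution (the reference acquisition is
4,608×3,072 px per plot from ~80 cm); the same plot seen from a ~50 m UAV
flight is only ~488×193 px.  :func:`degrade_resolution` emulates the aerial
platform by integer block-mean downsampling, which creates genuine mixed
vegetation/soil pixels at canopy boundaries — the mechanism that drives
ground-vs-aerial divergence of threshold-based cover indices.

Coordinates are 0-based, row-major; crop rectangles are half-open.
CSV tables are comma-separated UTF-8 with "." decimals and a mandatory
header; numeric cells are written with 6 significant digits and undefined
values (NaN) as empty cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .records import PlotRecord
from .spectral_indices import BandStack

__all__ = [
    "RgbImage", "PlotRegion", "PlotGrid",
    "read_rgb_image", "write_rgb_image",
    "read_band_stack", "write_band_stack",
    "crop_plot_grid", "degrade_resolution",
    "write_index_table", "read_index_table",
    "GROUND_PLOT_SIZE", "AERIAL_PLOT_SIZE", "DEFAULT_DOWNSAMPLE_FACTOR",
]

logger = logging.getLogger(__name__)

#: reference per-plot pixel sizes (width, height) at the two platforms
GROUND_PLOT_SIZE = (4608, 3072)
AERIAL_PLOT_SIZE = (488, 193)
#: default block-mean factor; the printed ground/aerial linear ratios are
#: 4608/488 ~ 9.4 and 3072/193 ~ 15.9, so one integer factor cannot match
#: both axes — 10 is the documented compromise
DEFAULT_DOWNSAMPLE_FACTOR = 10


@dataclass
class RgbImage:
    """8-bit 3-channel plot image with provenance tags."""

    pixels: np.ndarray
    plot_id: str | None = None
    platform: str = "ground"

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if arr.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {arr.dtype}")
        if self.platform not in ("ground", "aerial"):
            raise ValueError("platform must be 'ground' or 'aerial'")
        self.pixels = arr

    @property
    def pixels_per_plot(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.pixels.shape[1], self.pixels.shape[0])


@dataclass(frozen=True)
class PlotRegion:
    """Half-open rectangle [row, row+height) x [col, col+width)."""

    plot_id: str
    row: int
    col: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1 or self.row < 0 or self.col < 0:
            raise ValueError(f"invalid region for plot {self.plot_id!r}")


@dataclass(frozen=True)
class PlotGrid:
    regions: tuple[PlotRegion, ...]

    def __post_init__(self):
        regions = tuple(self.regions)
        ids = [r.plot_id for r in regions]
        if len(set(ids)) != len(ids):
            raise ValueError("plot ids in a grid must be unique")
        object.__setattr__(self, "regions", regions)

    def __len__(self):
        return len(self.regions)


def read_rgb_image(path, plot_id: str | None = None, platform: str = "ground") -> RgbImage:
    """Read a PNG/TIFF/JPEG plot image as 8-bit RGB.

    16-bit input is rescaled to 8-bit by max-value mapping (65535 → 255,
    logged); single-channel input is promoted to RGB by replication with a
    warning.  Any other channel count is a format error; unreadable files
    raise ``OSError``.
    """
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        warnings.warn(f"{path}: grayscale image promoted to RGB by replication",
                      stacklevel=2)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 1:
        warnings.warn(f"{path}: grayscale image promoted to RGB by replication",
                      stacklevel=2)
        arr = np.repeat(arr, 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 1 or 3 channels, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        logger.info("%s: 16-bit image rescaled to 8-bit (max-value mapping)", path)
        arr = np.rint(arr.astype(float) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return RgbImage(pixels=arr, plot_id=plot_id, platform=platform)


def write_rgb_image(image: RgbImage, path) -> None:
    iio.imwrite(Path(path), image.pixels)


def read_band_stack(directory, manifest: str = "bands.csv",
                    plot_id: str | None = None) -> BandStack:
    """Read a per-band TIFF stack described by a plain-text manifest.

    The manifest has one ``wavelength_nm,filename`` line per band (no
    header), filenames relative to ``directory``.  Bands are float
    reflectance maps in [0, 1] (integer TIFFs are rescaled by dtype max).
    """
    directory = Path(directory)
    bands: dict[int, np.ndarray] = {}
    for line in (directory / manifest).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        wl_s, fname = [part.strip() for part in line.split(",", 1)]
        arr = tifffile.imread(directory / fname)
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        bands[int(wl_s)] = np.clip(arr.astype(float), 0.0, 1.0)
    return BandStack(bands=bands, plot_id=plot_id)


def write_band_stack(stack: BandStack, directory, manifest: str = "bands.csv") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for wl in stack.wavelengths:
        fname = f"band_{wl}.tif"
        tifffile.imwrite(directory / fname, stack.bands[wl].astype(np.float32))
        lines.append(f"{wl},{fname}")
    (directory / manifest).write_text("\n".join(lines) + "\n")


def _crop_one(source, region: PlotRegion):
    r0, c0 = region.row, region.col
    r1, c1 = r0 + region.height, c0 + region.width
    if isinstance(source, RgbImage):
        h, w = source.pixels.shape[:2]
        if r1 > h or c1 > w:
            raise ValueError(f"region for plot {region.plot_id!r} exceeds mosaic bounds ({h}x{w})")
        return RgbImage(pixels=source.pixels[r0:r1, c0:c1].copy(),
                        plot_id=region.plot_id, platform=source.platform)
    if isinstance(source, BandStack):
        h, w = source.shape
        if r1 > h or c1 > w:
            raise ValueError(f"region for plot {region.plot_id!r} exceeds mosaic bounds ({h}x{w})")
        bands = {wl: arr[r0:r1, c0:c1].copy() for wl, arr in source.bands.items()}
        mask = source.mask[r0:r1, c0:c1].copy() if source.mask is not None else None
        return BandStack(bands=bands, mask=mask, plot_id=region.plot_id)
    raise TypeError(f"cannot crop {type(source).__name__}")


def crop_plot_grid(mosaic, grid: PlotGrid) -> list:
    """Cut pixel-exact per-plot sub-images/stacks out of a flat mosaic."""
    return [_crop_one(mosaic, region) for region in grid.regions]


def degrade_resolution(image: RgbImage, factor: int) -> RgbImage:
    """Emulate the aerial platform by integer block-mean downsampling.

    The image is cropped to the largest multiple of ``factor`` on each axis,
    then each ``factor``×``factor`` block is replaced by its mean color
    (rounded to 8 bits).  The platform tag switches to ``"aerial"``.
    Factor 1 returns the image unchanged apart from the tag.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    arr = image.pixels
    h = (arr.shape[0] // factor) * factor
    w = (arr.shape[1] // factor) * factor
    if h == 0 or w == 0:
        raise ValueError(f"factor {factor} larger than image {arr.shape[:2]}")
    blocks = arr[:h, :w].astype(float).reshape(h // factor, factor, w // factor, factor, 3)
    means = blocks.mean(axis=(1, 3))
    out = np.rint(means).astype(np.uint8)
    return replace(image, pixels=out, platform="aerial")


def _records_to_frame(records) -> pd.DataFrame:
    rows = [r.to_row() if isinstance(r, PlotRecord) else dict(r) for r in records]
    if not rows:
        from .records import LEAF_TRAITS
        return pd.DataFrame(columns=["plot_id", "genotype", "treatment",
                                     "grain_yield", *LEAF_TRAITS])
    return pd.DataFrame(rows)


def write_index_table(records, path) -> pd.DataFrame:
    """Write plot records (or row dicts / a DataFrame) as a CSV index table.

    Numeric values carry 6 significant digits; NaN sentinels become empty
    cells (their count is logged).  Returns the written DataFrame.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = _records_to_frame(list(records))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(df):
        n_missing = int(df.isna().to_numpy().sum())
        if n_missing:
            logger.info("%s: %d undefined cells written empty", path, n_missing)
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
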