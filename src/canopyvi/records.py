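"""The per-plot record: one row of the study table.

A :class:`PlotRecord` ties together a plot's design cells (genotype,
phosphorus treatment), its agronomic outcome (grain yield, t·ha⁻¹), the
optional leaf traits (P content, chlorophyll, C/N chemistry, stable-isotope
compositions) and the image-derived summaries at each acquisition platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .rgb_indices import ColorSummary
from .spectral_indices import SpectralSummary

__all__ = ["PlotRecord", "TREATMENTS", "LEAF_TRAITS"]

TREATMENTS = ("NPF", "OP")  # no phosphorus fertilizer / optimal phosphorus

#: leaf-trait column names: P (mg/g DW), chlorophyll (SPAD units), N and C
#: (% dry mass), C/N ratio, delta 13C and delta 15N (per mil)
LEAF_TRAITS = ("leaf_p", "lcc", "leaf_n", "leaf_c", "c_to_n", "d13c", "d15n")


@dataclass
class PlotRecord:
    plot_id: str
    genotype: str
    treatment: str
    grain_yield: float
    leaf_p: float | None = None
    lcc: float | None = None
    leaf_n: float | None = None
    leaf_c: float | None = None
    c_to_n: float | None = None
    d13c: float | None = None
    d15n: float | None = None
    color_ground: ColorSummary | None = None
    color_aerial: ColorSummary | None = None
    spectral: SpectralSummary | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.grain_yield is not None and self.grain_yield < 0:
            raise ValueError("grain yield must be nonnegative")

    def to_row(self) -> dict:
        """Flatten to one table row (ground_/aerial_ prefixes for RGB indices)."""
        row = {
            "plot_id": self.plot_id,
            "genotype": self.genotype,
            "treatment": self.treatment,
            "grain_yield": self.grain_yield,
        }
        for trait in LEAF_TRAITS:
            v = getattr(self, trait)
            row[trait] = math.nan if v is None else v
        if self.color_ground is not None:
            row.update(self.color_ground.as_dict(prefix="ground_"))
        if self.color_aerial is not None:
            row.update(self.color_aerial.as_dict(prefix="aerial_"))
        if self.spectral is not None:
            row.update(self.spectral.as_dict())
        row.update(self.extra)
        return row
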