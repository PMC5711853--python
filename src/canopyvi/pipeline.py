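"""End-to-end pipeline: generate → extract → degrade → summarize →
correlate → stepwise, as one reproducible run.

Given a :class:`RunConfig`, :func:`run_pipeline` produces under the output
directory:

* ``index_table.csv`` — one row per plot: design cells, grain yield, leaf
  traits, RGB indices at ground and emulated-aerial resolution, spectral
  indices and per-band means;
* ``ground_vs_aerial.csv`` — per-index Pearson r between ground and
  degraded-aerial values over plots;
* ``correlations_grain_yield.csv`` / ``correlations_leaf_p.csv`` — every
  index against yield / leaf P within NPF, OP and Combined, with
  significance stars (* 0.05, ** 0.01, *** 0.001);
* ``stepwise_report.csv`` — forward-stepwise models of yield and leaf P on
  aerial RGB indices and on spectral indices, per treatment, with R², RSE,
  model p and per-term variance portions;
* ``manifest.json`` — the full configuration, seed and skip counts.

Reruns with the same config and seed are bit-identical for CSV contents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plot_io
from .plot_io import degrade_resolution, read_rgb_image, write_index_table
from .records import PlotRecord
from .rgb_indices import summarize_rgb_plot
from .spectral_indices import DEFAULT_SAVI_L, INDEX_NAMES, summarize_spectral_plot
from .stats import forward_stepwise, pearson_table, significance_stars
from .synthetic import TrialDesign, generate_trial

__all__ = ["RunConfig", "RunResult", "run_pipeline",
           "RGB_INDEX_FIELDS", "rgb_column", "attach_summaries"]

logger = logging.getLogger(__name__)

#: the ten RGB index fields of a ColorSummary, in report order
RGB_INDEX_FIELDS = ("intensity", "hue_deg", "saturation", "lightness",
                    "a_star", "b_star", "u_star", "v_star", "ga", "gga")


def rgb_column(platform: str, name: str) -> str:
    return f"{platform}_{name}"


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input mode is active: ``"synthetic"`` (the default; plots
    come from the trial generator) or ``"directory"`` (plot images listed in
    a CSV with at least ``plot_id``, ``treatment``, ``image`` columns and
    optionally ``genotype``, ``grain_yield`` and leaf traits).
    """

    mode: str = "synthetic"
    design: TrialDesign = field(default_factory=TrialDesign)
    input_dir: str | None = None
    plots_csv: str | None = None
    savi_L: float = DEFAULT_SAVI_L
    aggregation: str = "mean-reflectance"
    downsample_factor: int = plot_io.DEFAULT_DOWNSAMPLE_FACTOR
    alpha_enter: float = 0.05
    out_dir: str = "canopyvi_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("synthetic", "directory"):
            raise ValueError("mode must be 'synthetic' or 'directory'")
        if self.mode == "directory" and not (self.input_dir and self.plots_csv):
            raise ValueError("directory mode needs input_dir and plots_csv")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


@dataclass
class RunResult:
    table: pd.DataFrame
    paths: dict[str, Path]
    skipped: list[dict]


def attach_summaries(record: PlotRecord, rgb, stack=None, *,
                     downsample_factor: int, savi_L: float,
                     aggregation: str) -> PlotRecord:
    """Fill a record's ground/aerial color summaries and spectral summary."""
    record.color_ground = summarize_rgb_plot(rgb)
    aerial = degrade_resolution(rgb, downsample_factor)
    record.color_aerial = summarize_rgb_plot(aerial)
    if stack is not None:
        record.spectral = summarize_spectral_plot(stack, mode=aggregation, L=savi_L)
    return record


def _ground_vs_aerial_table(df: pd.DataFrame) -> pd.DataFrame:
    from scipy import stats as sps
    rows = []
    for name in RGB_INDEX_FIELDS:
        g = pd.to_numeric(df[rgb_column("ground", name)], errors="coerce")
        a = pd.to_numeric(df[rgb_column("aerial", name)], errors="coerce")
        ok = g.notna() & a.notna()
        if ok.sum() >= 3 and g[ok].nunique() > 1 and a[ok].nunique() > 1:
            r, p = sps.pearsonr(g[ok], a[ok])
        else:
            r, p = np.nan, np.nan
        rows.append({"index": name, "r": r, "p": p, "n": int(ok.sum()),
                     "significance": significance_stars(p)})
    return pd.DataFrame(rows)


def _flat_correlations(df: pd.DataFrame, index_cols, target: str) -> pd.DataFrame:
    table = pearson_table(df, index_cols, target)
    rows = []
    for idx in table.index:
        row = {"index": idx}
        for group in table.columns.get_level_values("group").unique():
            r = table.loc[idx, (group, "r")]
            p = table.loc[idx, (group, "p")]
            row[f"{group}_r"] = r
            row[f"{group}_p"] = p
            row[f"{group}_n"] = table.loc[idx, (group, "n")]
            row[f"{group}_sig"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)


def _stepwise_report(df: pd.DataFrame, alpha_enter: float) -> pd.DataFrame:
    candidate_sets = {
        "aerial_rgb": [rgb_column("aerial", f) for f in RGB_INDEX_FIELDS],
        "spectral": list(INDEX_NAMES),
    }
    rows = []
    for response in ("grain_yield", "leaf_p"):
        if response not in df.columns or df[response].isna().all():
            continue
        for treatment in ("NPF", "OP"):
            sub = df[df["treatment"] == treatment]
            for set_name, cands in candidate_sets.items():
                cands = [c for c in cands if c in df.columns]
                if not cands or len(sub) < 5:
                    continue
                res = forward_stepwise(sub, response, cands, alpha_enter=alpha_enter)
                rows.append({
                    "response": response,
                    "treatment": treatment,
                    "candidate_set": set_name,
                    "equation": res.equation(),
                    "n_terms": len(res.terms),
                    "r_squared": res.r_squared,
                    "rse": res.rse,
                    "model_p": res.model_p_value,
                    "portions": "; ".join(f"{t}={v:.2f}"
                                          for t, v in res.portions.items()),
                    "intercept_only": res.intercept_only,
                    "n_obs": res.n_obs,
                })
    return pd.DataFrame(rows)


def _load_directory_plots(config: RunConfig):
    """Yield (record, RgbImage) pairs from a plots CSV; skip unreadable images."""
    base = Path(config.input_dir)
    table = pd.read_csv(Path(config.plots_csv))
    skipped = []
    pairs = []
    for _, row in table.iterrows():
        plot_id = str(row["plot_id"])
        try:
            rgb = read_rgb_image(base / str(row["image"]), plot_id=plot_id)
        except (OSError, ValueError) as exc:
            logger.warning("skipping plot %s: %s", plot_id, exc)
            skipped.append({"plot_id": plot_id, "reason": str(exc)})
            continue
        record = PlotRecord(
            plot_id=plot_id,
            genotype=str(row.get("genotype", "")),
            treatment=str(row["treatment"]),
            grain_yield=float(row["grain_yield"]) if "grain_yield" in row and pd.notna(row["grain_yield"]) else 0.0,
            leaf_p=float(row["leaf_p"]) if "leaf_p" in row and pd.notna(row["leaf_p"]) else None,
        )
        pairs.append((record, rgb, None))
    return pairs, skipped


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.getLogger("canopyvi").setLevel(config.log_level.upper())

    skipped: list[dict] = []
    if config.mode == "synthetic":
        design = dataclasses.replace(config.design, seed=config.seed)
        plots = generate_trial(design)
        triples = [(p.record, p.rgb, p.stack) for p in plots]
    else:
        triples, skipped = _load_directory_plots(config)

    records = []
    for record, rgb, stack in triples:
        attach_summaries(record, rgb, stack,
                         downsample_factor=config.downsample_factor,
                         savi_L=config.savi_L, aggregation=config.aggregation)
        records.append(record)
    if not records:
        raise ValueError("no readable plots; nothing to analyze")

    paths: dict[str, Path] = {}
    df = write_index_table(records, out / "index_table.csv")
    paths["index_table"] = out / "index_table.csv"

    gva = _ground_vs_aerial_table(df)
    gva.to_csv(out / "ground_vs_aerial.csv", index=False, float_format="%.6g")
    paths["ground_vs_aerial"] = out / "ground_vs_aerial.csv"

    index_cols = ([rgb_column(p, f) for p in ("ground", "aerial")
                   for f in RGB_INDEX_FIELDS]
                  + [c for c in INDEX_NAMES if c in df.columns]
                  + [c for c in df.columns if c.startswith("b") and c[1:].isdigit()])
    for target, fname in (("grain_yield", "correlations_grain_yield.csv"),
                          ("leaf_p", "correlations_leaf_p.csv")):
        if target in df.columns and df[target].notna().sum() >= 3:
            flat = _flat_correlations(df, index_cols, target)
            flat.to_csv(out / fname, index=False, float_format="%.6g")
            paths[fname.removesuffix(".csv")] = out / fname

    sw = _stepwise_report(df, config.alpha_enter)
    sw.to_csv(out / "stepwise_report.csv", index=False, float_format="%.6g")
    paths["stepwise_report"] = out / "stepwise_report.csv"

    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "design"},
            "design": dataclasses.asdict(config.design),
        },
        "n_plots": len(records),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "outputs": sorted(p.name for p in paths.values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    paths["manifest"] = out / "manifest.json"
    return RunResult(table=df, paths=paths, skipped=skipped)
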