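"""End-to-end sample driver: tile loop, output tables, tile-wise maps.

``run_sample`` walks the tiled sample directory, quantifies every tile
that passes the tissue gate, appends co-staining ratio columns when
extra channels are configured, and writes a per-tile CSV (primary
output), an XLSX copy, a mean ± SEM summary, a ``run_config.json``
provenance file and, optionally, per-read-out tile maps.  The tile loop
is sequential; tiles are independent, so it is embarrassingly parallel
if a caller wants to shard it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .costain import RATIO_READOUTS, costain_ratios, overlap_mask
from .io_tiling import (
    BinaryMask,
    read_tiled_mask,
    tissue_mask_dir,
    vascular_mask_dir,
)
from .skeleton_metrics import (
    PipelineConfig,
    TileReadouts,
    apply_tissue_gate,
    build_skeleton_graph,
    compute_tile_readouts,
    fill_small_holes,
    local_thickness,
    prune_short_end_branches,
    skeletonize,
    split_compartments,
)

__all__ = [
    "SampleResult",
    "quantify_mask",
    "quantify_tile",
    "run_sample",
    "aggregate_sample",
    "render_tile_map",
    "READOUT_FIELDS",
]

logger = logging.getLogger(__name__)

READOUT_FIELDS = (
    "mean_vessel_diameter_um",
    "vascular_density_pct",
    "vessel_length_density_mm_per_mm2",
    "mean_branch_length_um",
    "branch_density_per_mm2",
    "tortuosity_index",
    "n_branches",
)

GLOBAL_FIELDS = (
    "cluster_density_per_mm2",
    "branchpoint_density_per_mm2",
    "endpoint_density_per_mm2",
)


@dataclass
class SampleResult:
    """Per-tile rows, sample summary and per-read-out tile-value grids."""

    per_tile: pd.DataFrame
    summary: pd.DataFrame
    grid_rows: int
    grid_cols: int
    maps: dict[str, np.ndarray]
    output_dir: Optional[Path] = None


def quantify_mask(
    mask: BinaryMask, tissue_area_px: int, cfg: PipelineConfig, row: int = 0, col: int = 0
) -> TileReadouts:
    """Run the measurement chain on one corrected binary mask."""
    thick = local_thickness(mask)
    skel = skeletonize(mask)
    graph = build_skeleton_graph(skel, thick, cfg.length_method, cfg.resample_spacing_px)
    graph = prune_short_end_branches(graph, cfg.prune_threshold_um, cfg.iterative_prune)
    above, below = split_compartments(graph, cfg.separation_threshold_um)
    return compute_tile_readouts(graph, above, below, tissue_area_px, cfg, row, col)


def quantify_tile(
    vascular: BinaryMask,
    tissue: BinaryMask,
    cfg: PipelineConfig,
    costains: dict[int, BinaryMask] | None = None,
    row: int = 0,
    col: int = 0,
) -> Optional[dict]:
    """Quantify one tile; return a flat result row or None (skipped).

    Co-stain channels are multiplied with the raw primary mask first;
    the identical correction chain (tissue gate, hole filling) is then
    applied to the overlap before re-running the skeleton pipeline.
    """
    gated = apply_tissue_gate(vascular, tissue)
    if gated is None:
        return None
    corrected = fill_small_holes(gated, cfg.close_radius_um)
    tissue_area_px = tissue.area_px()
    readouts = quantify_mask(corrected, tissue_area_px, cfg, row, col)
    out = flatten_readouts(readouts)
    for ch, cmask in (costains or {}).items():
        ov = overlap_mask(vascular, cmask)
        ov_gated = apply_tissue_gate(ov, tissue)
        assert ov_gated is not None  # tissue is non-empty here
        ov_corrected = fill_small_holes(ov_gated, cfg.close_radius_um)
        ov_readouts = quantify_mask(ov_corrected, tissue_area_px, cfg, row, col)
        ratios = costain_ratios(readouts, ov_readouts, channel=ch)
        for name, value in ratios.ratios_pct.items():
            out[f"{name}_ch{ch}_ratio_pct"] = value
    return out


def flatten_readouts(r: TileReadouts) -> dict:
    """One wide row: ``<readout>__<compartment>`` columns plus globals."""
    row: dict = {
        "tile_row": r.tile_row,
        "tile_col": r.tile_col,
        "tissue_area_mm2": r.tissue_area_mm2,
    }
    for comp in ("all", "above", "below"):
        c = getattr(r, comp)
        for f in READOUT_FIELDS:
            row[f"{f}__{comp}"] = getattr(c, f)
    for f in GLOBAL_FIELDS:
        row[f] = getattr(r, f)
    return row


def _validate_layout(sample_dir: Path, cfg: PipelineConfig) -> None:
    if not sample_dir.is_dir():
        raise FileNotFoundError(f"sample directory not found: {sample_dir}")
    if not tissue_mask_dir(sample_dir).is_dir():
        raise FileNotFoundError(f"missing tissue mask tiles: {tissue_mask_dir(sample_dir)}")
    for ch in range(1, cfg.n_channels + 1):
        d = vascular_mask_dir(sample_dir, ch)
        if not d.is_dir():
            raise FileNotFoundError(f"missing vascular mask tiles for channel {ch}: {d}")


def run_sample(
    sample_dir,
    cfg: PipelineConfig,
    output_dir=None,
    write_outputs: bool = True,
) -> SampleResult:
    """Loop over the acquisition tiles of a sample and quantify each.

    Tiles whose tissue mask is empty are skipped and produce no row.
    Results are written as CSV (primary), XLSX, a summary table and a
    ``run_config.json``; per-read-out maps are rendered when
    ``cfg.save_figures`` is set.  The run is deterministic for fixed
    inputs.
    """
    sample_dir = Path(sample_dir)
    _validate_layout(sample_dir, cfg)
    cal = cfg.calibration_um_per_px
    tissue_ts = read_tiled_mask(tissue_mask_dir(sample_dir), cal, "tissue")
    channels = {
        ch: read_tiled_mask(vascular_mask_dir(sample_dir, ch), cal, "vascular")
        for ch in range(1, cfg.n_channels + 1)
    }
    for ch, ts in channels.items():
        if (ts.grid_rows, ts.grid_cols) != (tissue_ts.grid_rows, tissue_ts.grid_cols):
            raise ValueError(f"channel {ch} tile grid does not match the tissue tile grid")

    rows = []
    for idx, (r, c, tissue_tile) in enumerate(tissue_ts):
        vascular_tile = channels[1].tiles[idx][2]
        costains = {ch: channels[ch].tiles[idx][2] for ch in range(2, cfg.n_channels + 1)}
        result = quantify_tile(vascular_tile, tissue_tile, cfg, costains, row=r, col=c)
        if result is None:
            logger.info("tile (%d, %d): skipped (no tissue)", r, c)
            continue
        logger.info("tile (%d, %d): %d branches", r, c, result["n_branches__all"])
        rows.append(result)

    per_tile = pd.DataFrame(rows)
    summary = aggregate_sample(per_tile)
    maps = _tile_value_grids(per_tile, tissue_ts.grid_rows, tissue_ts.grid_cols)

    out_dir: Optional[Path] = None
    if write_outputs:
        out_dir = Path(output_dir) if output_dir is not None else sample_dir / "results"
        out_dir.mkdir(parents=True, exist_ok=True)
        per_tile.to_csv(out_dir / "per_tile.csv", index=False)
        per_tile.to_excel(out_dir / "per_tile.xlsx", index=False)
        summary.to_csv(out_dir / "summary.csv")
        (out_dir / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True) + "\n"
        )
        if cfg.save_figures:
            _write_maps(maps, out_dir / "maps")
    return SampleResult(per_tile, summary, tissue_ts.grid_rows, tissue_ts.grid_cols, maps, out_dir)


def aggregate_sample(per_tile: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM per read-out over the non-skipped tiles of a sample.

    Missing cells are excluded and the SEM denominator adjusted; with a
    single contributing tile the SEM is missing.  Zero rows yield an
    empty summary.
    """
    if per_tile.empty:
        return pd.DataFrame(columns=["mean", "sem", "n"])
    cols = [c for c in per_tile.columns if c not in ("tile_row", "tile_col")]
    recs = {}
    for c in cols:
        vals = per_tile[c].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        mean = float(vals.mean()) if n else float("nan")
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        recs[c] = {"mean": mean, "sem": sem, "n": n}
    return pd.DataFrame(recs).T[["mean", "sem", "n"]]


def _tile_value_grids(per_tile: pd.DataFrame, rows: int, cols: int) -> dict[str, np.ndarray]:
    grids: dict[str, np.ndarray] = {}
    if per_tile.empty:
        return grids
    for c in per_tile.columns:
        if c in ("tile_row", "tile_col"):
            continue
        g = np.full((rows, cols), np.nan)
        g[per_tile["tile_row"].astype(int), per_tile["tile_col"].astype(int)] = per_tile[
            c
        ].to_numpy(dtype=float)
        grids[c] = g
    return grids


def render_tile_map(
    values: np.ndarray, cell_px: int = 16, cmap: str = "viridis", colorbar: bool = False
) -> np.ndarray:
    """Render one per-tile value grid as an RGB image.

    Each tile becomes a ``cell_px`` × ``cell_px`` block colored by the
    colormap over the [min, max] range of the present values; skipped /
    no-tissue cells are pure black.  With ``colorbar`` a vertical scale
    bar is baked into a right-hand margin.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("tile-value grid must be a non-empty 2D array")
    import matplotlib

    colormap = matplotlib.colormaps[cmap]
    finite = np.isfinite(values)
    rgb_small = np.zeros(values.shape + (3,), dtype=np.uint8)
    if finite.any():
        lo, hi = values[finite].min(), values[finite].max()
        norm = np.zeros_like(values)
        if hi > lo:
            norm[finite] = (values[finite] - lo) / (hi - lo)
        else:
            norm[finite] = 0.5
        colored = (colormap(norm)[:, :, :3] * 255).astype(np.uint8)
        rgb_small[finite] = colored[finite]
    out = np.kron(rgb_small, np.ones((cell_px, cell_px, 1), dtype=np.uint8))
    if colorbar:
        h = out.shape[0]
        bar_w = max(8, cell_px)
        grad = np.linspace(1.0, 0.0, h)
        bar = (colormap(grad)[:, :3] * 255).astype(np.uint8)
        bar = np.repeat(bar[:, None, :], bar_w, axis=1)
        sep = np.full((h, 2, 3), 255, dtype=np.uint8)
        out = np.concatenate([out, sep, bar], axis=1)
    return out


def _write_maps(maps: dict[str, np.ndarray], map_dir: Path) -> None:
    from matplotlib.image import imsave

    map_dir.mkdir(parents=True, exist_ok=True)
    for name, grid in maps.items():
        img = render_tile_map(grid, cell_px=16, colorbar=True)
        imsave(map_dir / f"{name}.png", img)
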