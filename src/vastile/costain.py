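"""Co-staining overlap quantification.

For each additional staining channel (channels 2 and 3), the
non-overlapping signal is removed by multiplying the co-stain vascular
mask with the primary (channel 1) vascular mask, the full quantification
chain is re-run on the overlap mask, and every morphometric read-out is
expressed as a percentage of the primary channel's value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .io_tiling import BinaryMask
from .skeleton_metrics import CompartmentReadouts, TileReadouts

__all__ = ["CostainRatios", "overlap_mask", "costain_ratios", "RATIO_READOUTS"]

# read-outs for which a ratio is reported (whole-graph compartment)
RATIO_READOUTS = (
    "mean_vessel_diameter_um",
    "vascular_density_pct",
    "vessel_length_density_mm_per_mm2",
    "mean_branch_length_um",
    "branch_density_per_mm2",
    "tortuosity_index",
)


@dataclass
class CostainRatios:
    """Percentage ratios overlap/primary per read-out for one channel.

    A ratio is missing (NaN) when the primary read-out is 0 or itself
    missing — never 0 and never infinite.
    """

    channel: int
    ratios_pct: dict[str, float]


def overlap_mask(primary: BinaryMask, costain: BinaryMask) -> BinaryMask:
    """Pixel-wise AND of the primary and co-stain vascular masks."""
    if primary.shape != costain.shape:
        raise ValueError(f"shape mismatch: {primary.shape} vs {costain.shape}")
    return BinaryMask(
        primary.pixels & costain.pixels,
        primary.calibration_um_per_px,
        semantics="overlap",
        name=primary.name,
    )


def _ratio(num: float, den: float) -> float:
    if not math.isfinite(den) or den == 0 or not math.isfinite(num):
        return float("nan")
    return 100.0 * num / den


def costain_ratios(
    primary: TileReadouts, overlap: TileReadouts, channel: int = 2
) -> CostainRatios:
    """Element-wise percentage ratios of overlap vs primary read-outs.

    Both read-out sets must come from the same tile, tissue mask and
    configuration; ratios are computed on the whole-graph ("all")
    compartment.
    """
    if (primary.tile_row, primary.tile_col) != (overlap.tile_row, overlap.tile_col):
        raise ValueError("primary and overlap read-outs come from different tiles")
    if abs(primary.tissue_area_mm2 - overlap.tissue_area_mm2) > 1e-12:
        raise ValueError("primary and overlap read-outs use different tissue areas")
    out = {}
    for name in RATIO_READOUTS:
        out[name] = _ratio(getattr(overlap.all, name), getattr(primary.all, name))
    for name in (
        "cluster_density_per_mm2",
        "branchpoint_density_per_mm2",
        "endpoint_density_per_mm2",
    ):
        out[name] = _ratio(getattr(overlap, name), getattr(primary, name))
    return CostainRatios(channel=channel, ratios_pct=out)
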