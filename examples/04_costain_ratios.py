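"""Co-staining ratios: what fraction of the vasculature is double
positive for a second marker.

Channel 2 here stains half of the tubes; the pipeline multiplies the
two vascular masks, re-runs the full skeleton analysis on the overlap,
and reports every read-out as a percentage of channel 1.
"""

import tempfile
from pathlib import Path

import numpy as np

from vastile import BinaryMask, PipelineConfig, generate_network, run_sample
from vastile.synthetic import write_sample

image, tissue, vascular, gt = generate_network(
    6, widths=[8], noise_sd=0.0, seed=31, image_shape=(360, 360)
)
half = np.zeros_like(vascular.pixels)
for m in gt.tube_masks[:3]:
    half |= m
channel2 = BinaryMask(half, 1.0, semantics="vascular")

with tempfile.TemporaryDirectory() as td:
    sample = write_sample(Path(td) / "s", image, tissue, vascular, gt,
                          costain_masks={2: channel2})
    cfg = PipelineConfig(calibration_um_per_px=1.0, prune_threshold_um=8.0,
                         n_channels=2)
    row = run_sample(sample, cfg).per_tile.iloc[0]

for name in ("vascular_density_pct", "vessel_length_density_mm_per_mm2",
             "branch_density_per_mm2", "mean_vessel_diameter_um"):
    print(f"{name:40s} ch2/ch1 = {row[f'{name}_ch2_ratio_pct']:.1f} %")
# With 3 of 6 identical tubes double-stained, the area, length and
# branch-count ratios are all ~50 % while the diameter ratio is ~100 %
# (the double-positive vessels are not systematically thinner).
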