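"""Deterministic generator of calibrated vessel-network phantoms.

The generator paints disk-capped tubes of known width along analytic
centerlines onto a calibrated canvas, adds Gaussian background noise,
and returns the image together with exact ground truth: per-tube width,
analytic length, tortuosity and compartment label, plus network totals
(painted area, branch/junction/endpoint/cluster counts).  It stands in
for real microscopy data in every test, so recovered morphometry can be
checked against construction.

Straight tubes are drawn at orientations from a digitization-exact
angle set (multiples of 45° by default) so their rasterised centerline
length matches the analytic length; pass ``angle_set=None`` for
arbitrary orientations.  Tube centerlines sit on half-integer pixel
coordinates so an even nominal width rasterises to exactly that many
pixel rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tiling import (
    BinaryMask,
    CalibratedImage,
    tissue_mask_dir,
    vascular_mask_dir,
    write_image,
    write_tiled_mask,
)

__all__ = ["TubeRecord", "GroundTruth", "draw_tube", "generate_network", "write_sample"]


@dataclass
class TubeRecord:
    """Ground truth for a single painted tube."""

    tube_id: int
    width_px: float
    length_um: float
    euclidean_um: float
    tortuosity: float
    compartment: str  # "above" | "below" at the stated threshold
    painted_area_px: int
    centerline: np.ndarray  # (N, 2) float, (row, col)


@dataclass
class GroundTruth:
    """Per-tube table plus network totals for one phantom."""

    tubes: list[TubeRecord]
    area_px: int
    tissue_area_px: int
    n_branches: int | None
    n_junctions: int | None
    n_endpoints: int | None
    n_clusters: int | None
    separation_threshold_um: float
    tube_masks: list[np.ndarray] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tube_id": [t.tube_id for t in self.tubes],
                "width_px": [t.width_px for t in self.tubes],
                "length_um": [t.length_um for t in self.tubes],
                "euclidean_um": [t.euclidean_um for t in self.tubes],
                "tortuosity": [t.tortuosity for t in self.tubes],
                "compartment": [t.compartment for t in self.tubes],
                "painted_area_px": [t.painted_area_px for t in self.tubes],
            }
        )


def _distance_to_polyline(shape: tuple[int, int], pts: np.ndarray, radius: float) -> np.ndarray:
    """Boolean raster of pixels whose center lies within ``radius`` of
    the polyline (computed on the polyline's bounding window only)."""
    h, w = shape
    i0 = max(0, int(np.floor(pts[:, 0].min() - radius - 1)))
    i1 = min(h, int(np.ceil(pts[:, 0].max() + radius + 2)))
    j0 = max(0, int(np.floor(pts[:, 1].min() - radius - 1)))
    j1 = min(w, int(np.ceil(pts[:, 1].max() + radius + 2)))
    ii, jj = np.mgrid[i0:i1, j0:j1]
    P = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(np.float64)
    dmin = np.full(P.shape[0], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            proj = np.broadcast_to(a, P.shape)
        else:
            t = np.clip(((P - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
        d = np.hypot(P[:, 0] - proj[:, 0], P[:, 1] - proj[:, 1])
        np.minimum(dmin, d, out=dmin)
    out = np.zeros(shape, dtype=bool)
    out[i0:i1, j0:j1] = (dmin <= radius).reshape(i1 - i0, j1 - j0)
    return out


def draw_tube(
    canvas: CalibratedImage, centerline: np.ndarray, width_px: float, intensity: int
) -> np.ndarray:
    """Paint a disk-capped tube onto the canvas; return the painted set.

    Every pixel whose center lies within ``width_px / 2`` of the
    centerline polyline is set to ``intensity``.  End caps are rounded
    so local thickness at tube ends is well defined.  The centerline
    must keep a margin of at least the tube width from the canvas edge.
    """
    pts = np.asarray(centerline, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centerline must be an (N, 2) array of (row, col) points")
    if len(pts) == 1:
        pts = np.vstack([pts, pts])
    h, w = canvas.shape
    m = width_px
    if (
        pts[:, 0].min() < m
        or pts[:, 1].min() < m
        or pts[:, 0].max() > h - 1 - m
        or pts[:, 1].max() > w - 1 - m
    ):
        raise ValueError("centerline too close to the canvas edge (margin >= width required)")
    painted = _distance_to_polyline((h, w), pts, width_px / 2.0)
    canvas.pixels[painted] = np.uint8(intensity)
    return painted


def _polyline_length(pts: np.ndarray) -> float:
    d = np.diff(pts, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _straight_centerline(rng, shape, length_px, margin, angle_set):
    h, w = shape
    if angle_set is not None:
        ang = math.radians(float(rng.choice(list(angle_set))))
    else:
        ang = rng.uniform(0.0, math.pi)
    d = np.array([math.sin(ang), math.cos(ang)])
    half = length_px / 2.0 * d
    lo0, hi0 = margin + abs(half[0]), h - 1 - margin - abs(half[0])
    lo1, hi1 = margin + abs(half[1]), w - 1 - margin - abs(half[1])
    if hi0 <= lo0 or hi1 <= lo1:
        return None
    c = np.array(
        [math.floor(rng.uniform(lo0, hi0)) + 0.5, math.floor(rng.uniform(lo1, hi1)) + 0.5]
    )
    return np.vstack([c - half, c + half])


def _sinusoid_centerline(rng, shape, length_px, margin, amplitude, period):
    h, w = shape
    horizontal = bool(rng.integers(0, 2))
    span = length_px
    lim_main = (w if horizontal else h) - 1
    lim_cross = (h if horizontal else w) - 1
    if lim_main - 2 * margin - span <= 0 or lim_cross - 2 * (margin + amplitude) <= 0:
        return None
    start = math.floor(rng.uniform(margin, lim_main - margin - span)) + 0.5
    base = math.floor(rng.uniform(margin + amplitude, lim_cross - margin - amplitude)) + 0.5
    phase = rng.uniform(0, 2 * math.pi)
    xs = np.arange(0.0, span + 0.25, 0.5)
    ys = amplitude * np.sin(2 * math.pi * xs / period + phase)
    ys -= ys[0]  # chord endpoints at equal cross-axis offset is not needed; anchor start
    if horizontal:
        return np.stack([base + ys, start + xs], axis=1)
    return np.stack([start + xs, base + ys], axis=1)


def _random_walk_centerline(rng, shape, length_px, margin):
    h, w = shape
    step = 2.0
    n = max(2, int(length_px / step))
    for _ in range(20):
        heading = rng.uniform(0, 2 * math.pi)
        p = np.array(
            [rng.uniform(margin * 2, h - 1 - margin * 2), rng.uniform(margin * 2, w - 1 - margin * 2)]
        )
        pts = [p.copy()]
        ok = True
        for _ in range(n):
            heading += rng.normal(0.0, 0.15)
            p = p + step * np.array([math.sin(heading), math.cos(heading)])
            if not (margin < p[0] < h - 1 - margin and margin < p[1] < w - 1 - margin):
                ok = False
                break
            pts.append(p.copy())
        if ok and len(pts) >= 2:
            return np.asarray(pts)
    return None


def generate_network(
    n_tubes: int,
    width_range_px=(4, 16),
    tortuosity_mode: str = "straight",
    noise_sd: float = 5.0,
    tissue_shape: str = "full",
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    calibration_um_per_px: float = 1.0,
    vessel_intensity: int = 200,
    background_level: float = 15.0,
    outside_level: float = 2.0,
    outside_noise_sd: float = 1.0,
    separation_threshold_um: float = 10.0,
    length_range_px: tuple[float, float] = (120.0, 180.0),
    angle_set=(0.0, 45.0, 90.0, 135.0),
    sinusoid_amplitude_px: float = 8.0,
    sinusoid_period_px: float = 150.0,
    min_separation_px: int = 6,
    widths=None,
    non_overlapping: bool = True,
    avoid_tile_boundaries: tuple[int, int] | None = None,
    boundary_margin_px: int = 2,
    max_tries: int = 400,
) -> tuple[CalibratedImage, BinaryMask, BinaryMask, GroundTruth]:
    """Generate a calibrated phantom image with exact ground truth.

    Returns ``(image, tissue_mask, vascular_truth_mask, ground_truth)``.
    All randomness flows from the single explicit ``seed``; the same
    seed reproduces the output bit for bit.  ``widths`` may list exact
    tube widths assigned round-robin; otherwise widths are drawn
    uniformly from ``width_range_px``.  With ``non_overlapping`` (the
    default) tubes keep ``min_separation_px`` clearance, so network
    totals follow from construction: n_tubes branches and clusters, no
    junctions, two endpoints per tube.

    ``avoid_tile_boundaries=(th, tw)`` keeps every tube clear of the
    boundaries of a th × tw tile grid (plus ``boundary_margin_px``).
    Tile-wise quantification of such a phantom is free of cut
    artifacts, so tissue-area-weighted tile read-outs are exactly
    additive; vessels crossing tile cuts are a known bias of any
    tile-wise analysis and are deliberately excluded here.
    """
    if tortuosity_mode not in ("straight", "sinusoid", "random-walk"):
        raise ValueError("tortuosity_mode must be straight | sinusoid | random-walk")
    if tissue_shape not in ("full", "disk"):
        raise ValueError("tissue_shape must be 'full' or 'disk'")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    cal = calibration_um_per_px

    if tissue_shape == "disk":
        ii, jj = np.mgrid[0:h, 0:w]
        r = min(h, w) / 2.0 - 2.0
        tissue_px = (ii - (h - 1) / 2.0) ** 2 + (jj - (w - 1) / 2.0) ** 2 <= r * r
    else:
        tissue_px = np.ones((h, w), dtype=bool)

    forbidden = np.zeros((h, w), dtype=bool)
    if avoid_tile_boundaries is not None:
        th, tw = avoid_tile_boundaries
        m = boundary_margin_px
        for i in range(th, h, th):
            forbidden[max(0, i - m) : i + m, :] = True
        for j in range(tw, w, tw):
            forbidden[:, max(0, j - m) : j + m] = True

    canvas = CalibratedImage(np.zeros((h, w), np.uint8), cal, name=f"synthetic_seed{seed}")
    occupied = np.zeros((h, w), dtype=bool)
    tubes: list[TubeRecord] = []
    tube_masks: list[np.ndarray] = []
    truth = np.zeros((h, w), dtype=bool)

    for k in range(n_tubes):
        if widths is not None:
            width = float(widths[k % len(widths)])
        else:
            width = float(rng.uniform(*width_range_px))
        placed = False
        for _ in range(max_tries):
            length = float(rng.uniform(*length_range_px))
            if tortuosity_mode == "straight":
                pts = _straight_centerline(rng, (h, w), length, width + 2, angle_set)
            elif tortuosity_mode == "sinusoid":
                pts = _sinusoid_centerline(
                    rng, (h, w), length, width + 2, sinusoid_amplitude_px, sinusoid_period_px
                )
            else:
                pts = _random_walk_centerline(rng, (h, w), length, width + 2)
            if pts is None:
                continue
            painted = _distance_to_polyline((h, w), pts, width / 2.0)
            if not painted.any() or not tissue_px[painted].all():
                continue
            if (painted & forbidden).any():
                continue
            if non_overlapping:
                grown = _distance_to_polyline((h, w), pts, width / 2.0 + min_separation_px)
                if (grown & occupied).any():
                    continue
            canvas.pixels[painted] = np.uint8(vessel_intensity)
            occupied |= painted
            truth |= painted
            L = _polyline_length(pts) * cal
            d = pts[-1] - pts[0]
            E = float(math.hypot(d[0], d[1])) * cal
            tubes.append(
                TubeRecord(
                    tube_id=k,
                    width_px=width,
                    length_um=L,
                    euclidean_um=E,
                    tortuosity=L / E if E > 0 else float("nan"),
                    compartment="above" if width * cal >= separation_threshold_um else "below",
                    painted_area_px=int(painted.sum()),
                    centerline=pts,
                )
            )
            tube_masks.append(painted)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place tube {k} without overlap after {max_tries} tries; "
                "reduce n_tubes or tube size"
            )

    # render: dark, near-homogeneous glass outside the tissue; noisy
    # autofluorescent baseline inside; bright vessels
    base = np.where(tissue_px, background_level, outside_level).astype(np.float64)
    base[truth] = float(vessel_intensity)
    sd = np.where(tissue_px, noise_sd, min(noise_sd, outside_noise_sd))
    noisy = base + sd * rng.normal(0.0, 1.0, size=(h, w))
    image = CalibratedImage(
        np.clip(np.round(noisy), 0, 255).astype(np.uint8), cal, name=canvas.name
    )

    gt = GroundTruth(
        tubes=tubes,
        area_px=int(truth.sum()),
        tissue_area_px=int(tissue_px.sum()),
        n_branches=n_tubes if non_overlapping else None,
        n_junctions=0 if non_overlapping else None,
        n_endpoints=2 * n_tubes if non_overlapping else None,
        n_clusters=n_tubes if non_overlapping else None,
        separation_threshold_um=separation_threshold_um,
        tube_masks=tube_masks,
    )
    tissue = BinaryMask(tissue_px, cal, semantics="tissue", name=image.name)
    vascular = BinaryMask(truth, cal, semantics="vascular", name=image.name)
    return image, tissue, vascular, gt


def write_sample(
    sample_dir,
    image: CalibratedImage,
    tissue: BinaryMask,
    vascular: BinaryMask,
    ground_truth: GroundTruth | None = None,
    tile_shape: tuple[int, int] | None = None,
    costain_masks: dict[int, BinaryMask] | None = None,
) -> Path:
    """Write a phantom as a complete sample directory.

    Produces the raw image, whole-image masks, acquisition tiles and a
    ground-truth CSV in the layout consumed by the pipeline.  With
    ``tile_shape=None`` the whole image becomes a single tile.
    """
    sample_dir = Path(sample_dir)
    sample_dir.mkdir(parents=True, exist_ok=True)
    th, tw = tile_shape if tile_shape is not None else image.shape
    write_image(sample_dir / "image.tif", image)
    write_tiled_mask(tissue_mask_dir(sample_dir), tissue, th, tw)
    write_tiled_mask(vascular_mask_dir(sample_dir, 1), vascular, th, tw)
    if costain_masks:
        for ch, m in costain_masks.items():
            write_tiled_mask(vascular_mask_dir(sample_dir, ch), m, th, tw)
    if ground_truth is not None:
        ground_truth.to_frame().to_csv(sample_dir / "ground_truth.csv", index=False)
    return sample_dir
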