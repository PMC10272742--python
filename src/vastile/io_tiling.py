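"""Calibrated image I/O, binary masks, and the tiled sample layout.

Images are plain 2D 8-bit grayscale grids with a user-supplied spatial
calibration in µm/pixel.  Binary masks are stored on disk as 8-bit TIFFs
with exactly two values: background = 0 and foreground = 255.

Whole-slide samples are organised as a directory tree that mirrors the
tiled acquisition:

    <sample>/
        tissue_mask.tif                 # whole-image copy
        tissue_mask/tile_r{R}_c{C}.tif  # acquisition tiles
        vascular_mask_ch1.tif
        vascular_mask_ch1/tile_r{R}_c{C}.tif
        vascular_mask_ch2/...           # optional co-staining channels

Coordinates are 0-based and row-major; a pixel covers the half-open cell
[i, i+1) x [j, j+1); tile bounds are half-open and edge tiles are
truncated, never padded, so per-tile tissue-area normalisation is exact.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import tifffile

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "TileSet",
    "read_calibrated_image",
    "read_mask",
    "write_image",
    "write_mask",
    "split_into_tiles",
    "reassemble",
    "tile_filename",
    "parse_tile_filename",
    "tissue_mask_dir",
    "vascular_mask_dir",
    "write_tiled_mask",
    "read_tiled_mask",
]

MASK_SEMANTICS = ("tissue", "vascular", "roi", "overlap", "skeleton")

_TILE_RE = re.compile(r"^tile_r(\d+)_c(\d+)\.tiff?$")


@dataclass
class CalibratedImage:
    """A 2D 8-bit grayscale image with a µm/pixel calibration."""

    pixels: np.ndarray
    calibration_um_per_px: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie within [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration_um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A 2D boolean grid sharing an image's shape and calibration.

    ``semantics`` records what the mask means (tissue, vascular, roi,
    overlap, skeleton); it is carried along but never changes behaviour.
    """

    pixels: np.ndarray
    calibration_um_per_px: float
    semantics: str = "vascular"
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        if self.pixels.dtype != bool:
            vals = np.unique(self.pixels)
            if not np.all(np.isin(vals, (0, 255))) and not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask pixels must be boolean or 8-bit {0, 255}")
            self.pixels = self.pixels > 0
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration_um_per_px must be positive")
        if self.semantics not in MASK_SEMANTICS:
            raise ValueError(f"unknown mask semantics {self.semantics!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())

    def to_uint8(self) -> np.ndarray:
        """8-bit on-disk representation: background 0, foreground 255."""
        return np.where(self.pixels, 255, 0).astype(np.uint8)


Grid = Union[CalibratedImage, BinaryMask]


@dataclass
class TileSet:
    """Row-major tiles of a source grid plus the grid geometry.

    ``tiles`` holds (row_index, col_index, tile) triples ordered
    row-major; edge tiles may be smaller than the nominal tile size.
    """

    tiles: list[tuple[int, int, Grid]]
    grid_rows: int
    grid_cols: int
    tile_height_px: int
    tile_width_px: int

    def __iter__(self) -> Iterator[tuple[int, int, Grid]]:
        return iter(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)


def _check_calibration_tags(tif: tifffile.TiffFile, calibration: float, path: Path) -> None:
    # The user-supplied calibration always wins; TIFF resolution tags are
    # only consulted to warn when they disagree.
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return
        num, den = xres.value
        if num == 0 or den == 0:
            return
        px_per_unit = num / den
        unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 0), None)
        if unit_um is None:
            return
        tag_cal = unit_um / px_per_unit
        if abs(tag_cal - calibration) / calibration > 0.01:
            warnings.warn(
                f"{path}: TIFF tags imply {tag_cal:.4g} µm/px but the supplied "
                f"calibration is {calibration:.4g} µm/px; using the supplied value",
                stacklevel=3,
            )
    except Exception:
        pass


def read_calibrated_image(path, calibration_um_per_px: float) -> CalibratedImage:
    """Read a single-channel 2D TIFF as an 8-bit calibrated image.

    Inputs of higher bit depth are rescaled to 0–255 by a linear
    min–max mapping.  3D stacks and RGB images are rejected: project or
    split channels first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        _check_calibration_tags(tif, calibration_um_per_px, path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a 2D single-channel image, got shape {arr.shape}; "
            "project z-stacks / split RGB channels before analysis"
        )
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) * (255.0 / (hi - lo))
        else:
            arr = np.zeros_like(arr)
        arr = np.round(arr).astype(np.uint8)
    return CalibratedImage(arr, calibration_um_per_px, name=path.stem)


def read_mask(path, calibration_um_per_px: float, semantics: str = "vascular") -> BinaryMask:
    """Read an 8-bit binary mask (strictly {0, 255} on disk)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be 2D, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError(f"{path}: mask values must be exactly {{0, 255}}, found {vals[:10]}")
    return BinaryMask(arr > 0, calibration_um_per_px, semantics=semantics, name=path.stem)


def write_image(path, image: CalibratedImage) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels)


def write_mask(path, mask: BinaryMask) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.to_uint8())


def split_into_tiles(source: Grid, tile_height_px: int, tile_width_px: int) -> TileSet:
    """Divide a grid into row-major tiles of the given nominal size.

    Edge tiles are truncated, never padded.  A tile size equal to the
    full image yields exactly one tile (whole-image mode).
    """
    if tile_height_px < 1 or tile_width_px < 1:
        raise ValueError("tile dimensions must be >= 1")
    h, w = source.shape
    rows = -(-h // tile_height_px)
    cols = -(-w // tile_width_px)
    tiles: list[tuple[int, int, Grid]] = []
    for r in range(rows):
        for c in range(cols):
            sl = (
                slice(r * tile_height_px, min((r + 1) * tile_height_px, h)),
                slice(c * tile_width_px, min((c + 1) * tile_width_px, w)),
            )
            tiles.append((r, c, replace(source, pixels=source.pixels[sl].copy())))
    return TileSet(tiles, rows, cols, tile_height_px, tile_width_px)


def reassemble(tileset: TileSet) -> Grid:
    """Stitch a complete tile set back into the source grid.

    Raises if any grid position is missing; the output is identical to
    the pre-split source.
    """
    index = {(r, c): t for r, c, t in tileset.tiles}
    for r in range(tileset.grid_rows):
        for c in range(tileset.grid_cols):
            if (r, c) not in index:
                raise ValueError(f"tile set is missing grid position ({r}, {c})")
    h = sum(index[(r, 0)].shape[0] for r in range(tileset.grid_rows))
    w = sum(index[(0, c)].shape[1] for c in range(tileset.grid_cols))
    template = index[(0, 0)]
    out = np.zeros((h, w), dtype=template.pixels.dtype)
    i = 0
    for r in range(tileset.grid_rows):
        j = 0
        th = index[(r, 0)].shape[0]
        for c in range(tileset.grid_cols):
            t = index[(r, c)]
            out[i : i + t.shape[0], j : j + t.shape[1]] = t.pixels
            j += t.shape[1]
        i += th
    return replace(template, pixels=out)


# ---------------------------------------------------------------------------
# sample directory layout


def tile_filename(row: int, col: int) -> str:
    return f"tile_r{row}_c{col}.tif"


def parse_tile_filename(name: str) -> tuple[int, int] | None:
    m = _TILE_RE.match(name)
    return (int(m.group(1)), int(m.group(2))) if m else None


def tissue_mask_dir(sample_dir) -> Path:
    return Path(sample_dir) / "tissue_mask"


def vascular_mask_dir(sample_dir, channel: int = 1) -> Path:
    return Path(sample_dir) / f"vascular_mask_ch{channel}"


def write_tiled_mask(directory, mask: BinaryMask, tile_height_px: int, tile_width_px: int) -> TileSet:
    """Write a mask both as a whole image and as acquisition tiles.

    The whole-image copy is written next to the tile directory as
    ``<directory>.tif``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mask(directory.with_suffix(".tif"), mask)
    ts = split_into_tiles(mask, tile_height_px, tile_width_px)
    for r, c, t in ts:
        write_mask(directory / tile_filename(r, c), t)
    return ts


def read_tiled_mask(directory, calibration_um_per_px: float, semantics: str = "vascular") -> TileSet:
    """Discover and read all tiles in a mask directory.

    The grid geometry is inferred from the tile file names; a hole in
    the grid raises with the missing position named.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"tile directory not found: {directory}")
    found: dict[tuple[int, int], Path] = {}
    for p in sorted(directory.iterdir()):
        rc = parse_tile_filename(p.name)
        if rc is not None:
            found[rc] = p
    if not found:
        raise ValueError(f"no tiles matching tile_r*_c*.tif in {directory}")
    rows = max(r for r, _ in found) + 1
    cols = max(c for _, c in found) + 1
    tiles = []
    for r in range(rows):
        for c in range(cols):
            if (r, c) not in found:
                raise ValueError(f"tile set in {directory} is missing grid position ({r}, {c})")
            tiles.append((r, c, read_mask(found[(r, c)], calibration_um_per_px, semantics)))
    th = tiles[0][2].shape[0]
    tw = tiles[0][2].shape[1]
    return TileSet(tiles, rows, cols, th, tw)
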