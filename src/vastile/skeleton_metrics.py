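"""Per-tile quantification core: hole filling, local thickness,
skeletonization, branch graph construction, pruning, diameter-based
compartment separation, and the morphometric read-outs.

The measurement chain for one tile is:

1. gate the vascular mask by the tissue mask (empty tissue → skip);
2. fill small enclosed holes in the vascular mask (close label radius);
3. compute the local thickness map — at every foreground pixel the
   diameter of the largest inscribed disk that covers it;
4. skeletonize to a 1-px, 8-connected, topology-preserving centerline;
5. build the skeleton graph: endpoints / junctions / branches, with
   branch length L, endpoint-to-endpoint Euclidean distance E,
   tortuosity T = L/E, and mean diameter d̄ sampled from the thickness
   map along the centerline (diameter encoding);
6. prune endpoint branches shorter than the prune-ends threshold and
   merge the resulting degree-2 junctions;
7. split branches into macro-/micro-vascular compartments by d̄ against
   the separation threshold;
8. normalise everything by the tissue area: vascular density
   (Σ d̄·L / tissue area, %), vessel length density (mm/mm²), branch /
   branchpoint / endpoint / cluster densities (#/mm²), mean diameter,
   mean branch length, tortuosity index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk
from skimage.morphology import skeletonize as _sk_skeletonize

from .io_tiling import BinaryMask

__all__ = [
    "PipelineConfig",
    "ThicknessMap",
    "BranchRecord",
    "SkeletonGraph",
    "CompartmentReadouts",
    "TileReadouts",
    "apply_tissue_gate",
    "fill_small_holes",
    "local_thickness",
    "skeletonize",
    "build_skeleton_graph",
    "prune_short_end_branches",
    "split_compartments",
    "compute_tile_readouts",
]

logger = logging.getLogger(__name__)

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class PipelineConfig:
    """All user parameters of a quantification run.

    calibration_um_per_px
        Spatial calibration of the input images (µm/pixel).
    separation_threshold_um
        Diameter cutoff splitting branches into the micro- (below) and
        macro-vascular (above) compartments.  Example brain value: 10.
    close_radius_um
        Close-label radius: enclosed holes with an equivalent diameter
        below twice this value are filled, followed by a morphological
        closing with a disk of this radius.  Example brain value: 3.
    prune_threshold_um
        Prune-ends threshold: endpoint branches shorter than this are
        removed from the skeleton.  Example brain value: 5.
    n_channels
        1–3; channels 2 and 3 are co-staining channels quantified on
        their overlap with channel 1.
    length_method
        "resampled" (default): branch length from an anchored polyline
        (Euclidean sums between every ``resample_spacing_px``-th path
        pixel), which is orientation-unbiased; "chamfer": 1/√2 step
        weights.
    diameter_weighting
        "branch" (default): tile mean vessel diameter is the unweighted
        mean over branches of d̄; "length": weighted by branch length.
    iterative_prune
        Re-prune until no short endpoint branch remains (default is a
        single pass).
    """

    calibration_um_per_px: float
    separation_threshold_um: float = 10.0
    close_radius_um: float = 3.0
    prune_threshold_um: float = 5.0
    n_channels: int = 1
    save_figures: bool = False
    length_method: str = "resampled"
    resample_spacing_px: int = 4
    diameter_weighting: str = "branch"
    iterative_prune: bool = False

    def __post_init__(self) -> None:
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration_um_per_px must be positive")
        if self.separation_threshold_um <= 0:
            raise ValueError("separation_threshold_um must be positive")
        if self.close_radius_um < 0 or self.prune_threshold_um < 0:
            raise ValueError("radii/thresholds must be nonnegative")
        if self.n_channels not in (1, 2, 3):
            raise ValueError("n_channels must be 1, 2 or 3")
        if self.length_method not in ("resampled", "chamfer"):
            raise ValueError("length_method must be 'resampled' or 'chamfer'")
        if self.diameter_weighting not in ("branch", "length"):
            raise ValueError("diameter_weighting must be 'branch' or 'length'")


@dataclass
class ThicknessMap:
    """Local thickness in µm on foreground pixels, 0 on background."""

    values: np.ndarray
    calibration_um_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BranchRecord:
    """One skeleton branch between two nodes.

    ``length_um`` (L) is the path length, ``euclidean_um`` (E) the
    straight-line distance between the branch's ends, ``tortuosity``
    the arc-chord ratio T = L/E, ``mean_diameter_um`` (d̄) the mean of
    the local-thickness values along the path, and ``area_um2`` the
    vessel-area estimate d̄·L.  For closed loops E is the maximum
    pointwise chord and ``is_loop`` is set.
    """

    pixel_path: np.ndarray
    length_um: float
    euclidean_um: float
    mean_diameter_um: float
    tortuosity: float
    area_um2: float
    end_types: tuple[str, str]
    end_nodes: tuple[object, object] = (None, None)
    is_loop: bool = False


@dataclass
class SkeletonGraph:
    """Branches plus node/cluster counts of one skeleton.

    Compartment views produced by :func:`split_compartments` carry
    branches only; their node and cluster counts are ``None`` because
    nodes are shared between compartments.
    """

    branches: list[BranchRecord]
    n_junctions: Optional[int]
    n_endpoints: Optional[int]
    n_clusters: Optional[int]
    calibration_um_per_px: float
    n_isolated_px: int = 0

    @property
    def n_branches(self) -> int:
        return len(self.branches)


# ---------------------------------------------------------------------------
# mask correction


def apply_tissue_gate(vascular: BinaryMask, tissue: BinaryMask) -> Optional[BinaryMask]:
    """AND the vascular mask with the tissue mask.

    Returns ``None`` (the skip signal) when the tissue tile is empty so
    the caller can move on to the next tile; vessel pixels outside the
    tissue never survive.
    """
    if vascular.shape != tissue.shape:
        raise ValueError(f"shape mismatch: vascular {vascular.shape} vs tissue {tissue.shape}")
    if not tissue.pixels.any():
        return None
    return BinaryMask(
        vascular.pixels & tissue.pixels,
        vascular.calibration_um_per_px,
        semantics="vascular",
        name=vascular.name,
    )


def fill_small_holes(mask: BinaryMask, close_radius_um: float) -> BinaryMask:
    """Fill small enclosed holes in the vascular mask.

    Background components fully enclosed by foreground whose equivalent
    diameter is below ``2 * close_radius_um`` are filled; a
    morphological closing with a disk of radius ``close_radius_um``
    follows.  A radius of 0 is the identity.
    """
    if close_radius_um < 0:
        raise ValueError("close_radius_um must be nonnegative")
    if close_radius_um == 0:
        return replace(mask, pixels=mask.pixels.copy())
    cal = mask.calibration_um_per_px
    fg = mask.pixels.copy()
    # enclosed background components (4-connected, complementary to the
    # 8-connected foreground) that do not touch the image border
    bg_lab, n_bg = ndimage.label(~fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_bg:
        border = np.zeros_like(fg)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touches = np.unique(bg_lab[border & (bg_lab > 0)])
        areas = np.bincount(bg_lab.ravel(), minlength=n_bg + 1)
        for lab in range(1, n_bg + 1):
            if lab in touches:
                continue
            equiv_diam_um = 2.0 * math.sqrt(areas[lab] / math.pi) * cal
            if equiv_diam_um < 2.0 * close_radius_um:
                fg[bg_lab == lab] = True
    r_px = int(round(close_radius_um / cal))
    if r_px >= 1:
        pad = r_px + 1
        padded = np.pad(fg, pad)
        closed = ndimage.binary_closing(padded, structure=_disk(r_px))
        fg = closed[pad:-pad, pad:-pad]
    return replace(mask, pixels=fg)


# ---------------------------------------------------------------------------
# local thickness


def local_thickness(mask: BinaryMask) -> ThicknessMap:
    """Largest-inscribed-disk diameter at every foreground pixel, in µm.

    At pixel p the value is ``2 * max{r(q) : |p - q| <= r(q)}`` with
    r(q) the Euclidean distance from foreground pixel q to the nearest
    background pixel — i.e. the diameter of the largest disk fully
    inside the foreground that covers p (sampled on the pixel-center
    lattice; diameters may overestimate the continuous value by up to
    one pixel).
    """
    fg = mask.pixels
    out = np.zeros(fg.shape, dtype=np.float64)
    if fg.any():
        rho = np.where(fg, ndimage.distance_transform_edt(fg), 0.0)
        out = _propagate_disks(fg, rho)
    return ThicknessMap(out * mask.calibration_um_per_px, mask.calibration_um_per_px)


def _propagate_disks(fg: np.ndarray, rho: np.ndarray) -> np.ndarray:
    # A center q is redundant when an 8-neighbour q' satisfies
    # rho(q') >= rho(q) + |q - q'|: its disk then lies inside q's disk.
    # This exact reduction leaves only ridge-like centers to paint.
    redundant = np.zeros_like(fg)
    h, w = fg.shape
    for di, dj in _EIGHT:
        d = math.hypot(di, dj)
        shifted = np.full_like(rho, -np.inf)
        src = rho[max(0, -di) : h - max(0, di), max(0, -dj) : w - max(0, dj)]
        shifted[max(0, di) : h - max(0, -di), max(0, dj) : w - max(0, -dj)] = src
        redundant |= fg & (shifted >= rho + d - 1e-9)
    cand = np.argwhere(fg & ~redundant)
    out = np.zeros_like(rho)
    order = np.argsort(-rho[tuple(cand.T)])
    for k in order:
        i, j = cand[k]
        r = rho[i, j]
        R = int(math.floor(r))
        i0, i1 = max(0, i - R), min(h, i + R + 1)
        j0, j1 = max(0, j - R), min(w, j + R + 1)
        ii, jj = np.mgrid[i0:i1, j0:j1]
        covered = (ii - i) ** 2 + (jj - j) ** 2 <= r * r + 1e-9
        sub = out[i0:i1, j0:j1]
        np.maximum(sub, np.where(covered, 2.0 * r, 0.0), out=sub)
    return np.where(fg, out, 0.0)


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """1-px-wide, 8-connected, topology-preserving centerline."""
    skel = _sk_skeletonize(mask.pixels)
    return BinaryMask(skel, mask.calibration_um_per_px, semantics="skeleton", name=mask.name)


# ---------------------------------------------------------------------------
# graph construction


def _neighbors(S: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
    h, w = S.shape
    out = []
    for di, dj in _EIGHT:
        i, j = p[0] + di, p[1] + dj
        if 0 <= i < h and 0 <= j < w and S[i, j]:
            out.append((i, j))
    return out


def _path_length_px(path: np.ndarray, method: str, spacing: int) -> float:
    if len(path) < 2:
        return 0.0
    if method == "chamfer":
        steps = np.abs(np.diff(path, axis=0))
        return float(np.where(steps.sum(axis=1) == 2, math.sqrt(2.0), 1.0).sum())
    anchors = list(range(0, len(path) - 1, spacing)) + [len(path) - 1]
    q = path[anchors].astype(np.float64)
    d = np.diff(q, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _max_chord_px(path: np.ndarray) -> float:
    p = path.astype(np.float64)
    if len(p) > 400:  # loops are small; subsample defensively
        p = p[:: max(1, len(p) // 400)]
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(axis=2)
    return float(math.sqrt(d2.max()))


def _make_branch(
    path: list[tuple[int, int]],
    thick_um: np.ndarray,
    cal: float,
    end_types: tuple[str, str],
    end_nodes: tuple[object, object],
    method: str,
    spacing: int,
) -> BranchRecord:
    arr = np.asarray(path)
    tvals = thick_um[tuple(arr.T)]
    if np.any(tvals <= 0):
        raise RuntimeError("skeleton pixel with zero local thickness (internal inconsistency)")
    L = _path_length_px(arr, method, spacing) * cal
    is_loop = end_nodes[0] is not None and end_nodes[0] == end_nodes[1]
    is_loop = is_loop or end_types == ("cycle", "cycle")
    if is_loop:
        E = _max_chord_px(arr) * cal
    else:
        d = arr[-1] - arr[0]
        E = math.hypot(d[0], d[1]) * cal
    dbar = float(tvals.mean())
    T = L / E if E > 0 else float("nan")
    return BranchRecord(
        pixel_path=arr,
        length_um=L,
        euclidean_um=E,
        mean_diameter_um=dbar,
        tortuosity=T,
        area_um2=dbar * L,
        end_types=end_types,
        end_nodes=end_nodes,
        is_loop=is_loop,
    )


def build_skeleton_graph(
    skeleton: BinaryMask,
    thickness: ThicknessMap,
    length_method: str = "resampled",
    resample_spacing_px: int = 4,
) -> SkeletonGraph:
    """Classify skeleton pixels and trace branches between nodes.

    Pixels are classified by their 8-neighbour count: 1 → endpoint,
    2 → slab, >= 3 → junction; 8-adjacent junction pixels merge into a
    single junction node.  Branch paths include their terminal node
    pixels.  Isolated single pixels form degenerate one-pixel clusters
    with no branch.  Slab-only cycles become closed loop branches.
    """
    if skeleton.shape != thickness.shape:
        raise ValueError("skeleton and thickness map shapes differ")
    cal = skeleton.calibration_um_per_px
    S = skeleton.pixels
    if not S.any():
        return SkeletonGraph([], 0, 0, 0, cal)
    nbr = ndimage.convolve(S.astype(np.int8), np.ones((3, 3), np.int8), mode="constant") - 1
    deg = np.where(S, nbr, -1)
    endpoint_px = deg == 1
    junction_px = deg >= 3
    isolated_px = deg == 0
    jlab, n_junctions = ndimage.label(junction_px, structure=np.ones((3, 3)))

    def node_id(p: tuple[int, int]):
        if junction_px[p]:
            return ("J", int(jlab[p]))
        return ("E", p)

    def node_type(p: tuple[int, int]) -> str:
        return "junction" if junction_px[p] else "endpoint"

    thick = thickness.values
    visited = np.zeros_like(S)
    branches: list[BranchRecord] = []
    seen_pairs: set[frozenset] = set()
    node_pixels = [tuple(p) for p in np.argwhere(endpoint_px | junction_px)]

    for p in node_pixels:
        for q in _neighbors(S, p):
            if endpoint_px[q] or junction_px[q]:
                if node_id(q) == node_id(p):
                    continue  # internal adjacency within one junction node
                pair = frozenset((p, q))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                branches.append(
                    _make_branch(
                        [p, q], thick, cal,
                        (node_type(p), node_type(q)), (node_id(p), node_id(q)),
                        length_method, resample_spacing_px,
                    )
                )
            elif deg[q] == 2 and not visited[q]:
                path = [p]
                prev, cur = p, q
                while True:
                    visited[cur] = True
                    path.append(cur)
                    nxts = [n for n in _neighbors(S, cur) if n != prev]
                    if not nxts:
                        break  # dead end (should not occur on slab pixels)
                    nxt = nxts[0]
                    if endpoint_px[nxt] or junction_px[nxt]:
                        path.append(nxt)
                        break
                    if visited[nxt]:
                        break  # defensive: already-claimed slab
                    prev, cur = cur, nxt
                last = path[-1]
                if endpoint_px[last] or junction_px[last]:
                    ends = (node_id(p), node_id(last))
                    types = (node_type(p), node_type(last))
                else:
                    ends = (node_id(p), node_id(p))
                    types = (node_type(p), node_type(p))
                branches.append(
                    _make_branch(path, thick, cal, types, ends, length_method, resample_spacing_px)
                )

    # pure cycles: remaining unvisited slab pixels, all of degree 2
    remaining = (deg == 2) & ~visited
    while remaining.any():
        start = tuple(np.argwhere(remaining)[0])
        path = [start]
        visited[start] = True
        prev, cur = start, _neighbors(S, start)[0]
        while cur != start:
            visited[cur] = True
            path.append(cur)
            nxts = [n for n in _neighbors(S, cur) if n != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
        path.append(start)
        branches.append(
            _make_branch(path, thick, cal, ("cycle", "cycle"), (None, None),
                         length_method, resample_spacing_px)
        )
        remaining = (deg == 2) & ~visited

    _, n_clusters = ndimage.label(S, structure=np.ones((3, 3)))
    return SkeletonGraph(
        branches,
        n_junctions=int(n_junctions),
        n_endpoints=int(endpoint_px.sum()),
        n_clusters=int(n_clusters),
        calibration_um_per_px=cal,
        n_isolated_px=int(isolated_px.sum()),
    )


# ---------------------------------------------------------------------------
# pruning


def _degrees(branches: list[BranchRecord]) -> dict:
    deg: dict = {}
    for b in branches:
        for n in b.end_nodes:
            if n is not None:
                deg[n] = deg.get(n, 0) + 1
    return deg


def _merge_pair(b1: BranchRecord, b2: BranchRecord, node, spacing_um: float) -> BranchRecord:
    # orient b1 to end at `node` and b2 to start at it
    p1 = b1.pixel_path if b1.end_nodes[1] == node else b1.pixel_path[::-1]
    n1 = b1.end_nodes[0] if b1.end_nodes[1] == node else b1.end_nodes[1]
    t1 = b1.end_types[0] if b1.end_nodes[1] == node else b1.end_types[1]
    p2 = b2.pixel_path if b2.end_nodes[0] == node else b2.pixel_path[::-1]
    n2 = b2.end_nodes[1] if b2.end_nodes[0] == node else b2.end_nodes[0]
    t2 = b2.end_types[1] if b2.end_nodes[0] == node else b2.end_types[0]
    if tuple(p1[-1]) == tuple(p2[0]):
        path = np.concatenate([p1, p2[1:]])
    else:
        path = np.concatenate([p1, p2])
    L = b1.length_um + b2.length_um
    dbar = (b1.mean_diameter_um * b1.length_um + b2.mean_diameter_um * b2.length_um) / L
    is_loop = n1 == n2
    if is_loop:
        E = _max_chord_px(path) * spacing_um
    else:
        d = path[-1].astype(float) - path[0].astype(float)
        E = math.hypot(d[0], d[1]) * spacing_um
    return BranchRecord(
        pixel_path=path,
        length_um=L,
        euclidean_um=E,
        mean_diameter_um=dbar,
        tortuosity=L / E if E > 0 else float("nan"),
        area_um2=dbar * L,
        end_types=(t1, t2),
        end_nodes=(n1, n2),
        is_loop=is_loop,
    )


def prune_short_end_branches(
    graph: SkeletonGraph, prune_threshold_um: float, iterative: bool = False
) -> SkeletonGraph:
    """Remove endpoint branches shorter than the prune-ends threshold.

    A branch qualifies when its length is below the threshold and at
    least one of its ends is a tip (a node of degree 1).  After removal,
    junctions left with exactly two incident branches merge them into
    one (lengths add, the Euclidean distance is recomputed from the new
    ends, and d̄ recombines length-weighted).  A threshold of 0 is the
    identity; the default is a single pruning pass.
    """
    if prune_threshold_um < 0:
        raise ValueError("prune_threshold_um must be nonnegative")
    branches = list(graph.branches)
    if prune_threshold_um == 0 or not branches:
        return replace(graph, branches=branches)
    cal = graph.calibration_um_per_px

    while True:
        deg = _degrees(branches)
        keep, removed = [], 0
        for b in branches:
            tip = (not b.is_loop) and any(
                n is not None and deg.get(n, 0) == 1 for n in b.end_nodes
            )
            if tip and b.length_um < prune_threshold_um:
                removed += 1
            else:
                keep.append(b)
        branches = keep
        # merge degree-2 nodes until none remain
        merged = True
        while merged:
            merged = False
            deg = _degrees(branches)
            for node, d in deg.items():
                if d != 2:
                    continue
                incident = [b for b in branches if node in b.end_nodes and not b.is_loop]
                if len(incident) != 2:
                    continue  # loop carrier: leave intact
                b1, b2 = incident
                branches = [b for b in branches if b is not b1 and b is not b2]
                branches.append(_merge_pair(b1, b2, node, cal))
                merged = True
                break
        if not iterative or removed == 0:
            break

    deg = _degrees(branches)
    n_endpoints = sum(1 for d in deg.values() if d == 1)
    n_junctions = sum(1 for d in deg.values() if d >= 3)
    n_junctions += sum(
        1 for node, d in deg.items() if d == 2
    )  # only loop carriers survive merging with degree 2

    # clusters: connected components over branches sharing nodes, plus
    # node-free cycles and isolated single-pixel clusters
    parent: dict = {}

    def find(a):
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    n_cycles = 0
    for i, b in enumerate(branches):
        ns = [n for n in b.end_nodes if n is not None]
        if not ns:
            n_cycles += 1
            continue
        key = ("B", i)
        for n in ns:
            union(key, n)
    roots = {find(k) for k in parent}
    n_clusters = len(roots) + n_cycles + graph.n_isolated_px

    return SkeletonGraph(
        branches,
        n_junctions=n_junctions,
        n_endpoints=n_endpoints,
        n_clusters=n_clusters,
        calibration_um_per_px=cal,
        n_isolated_px=graph.n_isolated_px,
    )


# ---------------------------------------------------------------------------
# compartments and read-outs


def split_compartments(
    graph: SkeletonGraph, separation_threshold_um: float
) -> tuple[SkeletonGraph, SkeletonGraph]:
    """Partition branches by mean diameter against the threshold.

    d̄ >= threshold → *above* (macrovascular), otherwise *below*
    (microvascular); ties go to *above*.  Every branch lands in exactly
    one compartment; node and cluster counts stay with the full graph.
    """
    above = [b for b in graph.branches if b.mean_diameter_um >= separation_threshold_um]
    below = [b for b in graph.branches if b.mean_diameter_um < separation_threshold_um]
    mk = lambda bs: SkeletonGraph(bs, None, None, None, graph.calibration_um_per_px)
    return mk(above), mk(below)


@dataclass
class CompartmentReadouts:
    """Morphometric read-outs of one branch set, tissue-normalised.

    Means over an empty branch set are NaN (missing), never 0, so
    averaging across tiles stays unbiased; densities of an empty set
    are 0.
    """

    n_branches: int
    total_length_um: float
    total_area_um2: float
    mean_vessel_diameter_um: float
    vascular_density_pct: float
    vessel_length_density_mm_per_mm2: float
    mean_branch_length_um: float
    branch_density_per_mm2: float
    tortuosity_index: float
    vascular_density_raw_pct: float


@dataclass
class TileReadouts:
    """Per-tile read-outs for the three compartments plus whole-graph
    node/cluster densities and the tissue-area denominator."""

    all: CompartmentReadouts
    above: CompartmentReadouts
    below: CompartmentReadouts
    cluster_density_per_mm2: float
    branchpoint_density_per_mm2: float
    endpoint_density_per_mm2: float
    tissue_area_mm2: float
    tile_row: int = 0
    tile_col: int = 0


def _compartment_readouts(
    branches: list[BranchRecord], area_mm2: float, weighting: str
) -> CompartmentReadouts:
    n = len(branches)
    total_L = float(sum(b.length_um for b in branches))
    total_A = float(sum(b.area_um2 for b in branches))
    density_raw = 100.0 * total_A / (area_mm2 * 1e6)
    if density_raw > 100.0:
        logger.info("vascular density estimate %.1f%% capped at 100%%", density_raw)
    density = min(density_raw, 100.0)
    if n == 0:
        mean_d = mean_L = tort = float("nan")
    else:
        if weighting == "length" and total_L > 0:
            mean_d = float(sum(b.mean_diameter_um * b.length_um for b in branches) / total_L)
        else:
            mean_d = float(np.mean([b.mean_diameter_um for b in branches]))
        mean_L = total_L / n
        ts = [b.tortuosity for b in branches if math.isfinite(b.tortuosity)]
        tort = float(np.mean(ts)) if ts else float("nan")
    return CompartmentReadouts(
        n_branches=n,
        total_length_um=total_L,
        total_area_um2=total_A,
        mean_vessel_diameter_um=mean_d,
        vascular_density_pct=density,
        vessel_length_density_mm_per_mm2=(total_L / 1000.0) / area_mm2,
        mean_branch_length_um=mean_L,
        branch_density_per_mm2=n / area_mm2,
        tortuosity_index=tort,
        vascular_density_raw_pct=density_raw,
    )


def compute_tile_readouts(
    graph: SkeletonGraph,
    above: SkeletonGraph,
    below: SkeletonGraph,
    tissue_area_px: int,
    cfg: PipelineConfig,
    tile_row: int = 0,
    tile_col: int = 0,
) -> TileReadouts:
    """Normalise graph measurements by the tissue area of the tile.

    With A_t the tissue area in mm²: vascular density =
    100·Σ(d̄·L)/A_t (capped at 100%), vessel length density = ΣL/A_t in
    mm/mm², and branch / branchpoint / endpoint / cluster densities are
    counts per mm².  Tiles with zero tissue area must be skipped
    upstream and raise here.
    """
    if tissue_area_px <= 0:
        raise ValueError("tissue_area_px must be positive; empty tiles are skipped upstream")
    cal = cfg.calibration_um_per_px
    area_mm2 = tissue_area_px * (cal / 1000.0) ** 2
    w = cfg.diameter_weighting
    return TileReadouts(
        all=_compartment_readouts(graph.branches, area_mm2, w),
        above=_compartment_readouts(above.branches, area_mm2, w),
        below=_compartment_readouts(below.branches, area_mm2, w),
        cluster_density_per_mm2=(graph.n_clusters or 0) / area_mm2,
        branchpoint_density_per_mm2=(graph.n_junctions or 0) / area_mm2,
        endpoint_density_per_mm2=(graph.n_endpoints or 0) / area_mm2,
        tissue_area_mm2=area_mm2,
        tile_row=tile_row,
        tile_col=tile_col,
    )
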