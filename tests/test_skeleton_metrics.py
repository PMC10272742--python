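"""Local thickness, skeleton graph construction, pruning, compartments
and tissue-normalised read-outs."""

import math

import numpy as np
import pytest
from scipy import ndimage

from vastile import (
    PipelineConfig,
    apply_tissue_gate,
    build_skeleton_graph,
    compute_tile_readouts,
    fill_small_holes,
    generate_network,
    local_thickness,
    prune_short_end_branches,
    quantify_mask,
    skeletonize,
    split_compartments,
)
from vastile.skeleton_metrics import BranchRecord, SkeletonGraph

from .conftest import constant_thickness, make_mask


def brute_force_thickness_px(fg):
    """Per-pixel exhaustive largest-inscribed-disk search.

    The disk centered at foreground pixel q has radius EDT(q); pixel p
    takes twice the largest radius among disks that cover it.
    """
    edt = ndimage.distance_transform_edt(fg)
    pts = np.argwhere(fg)
    rho = edt[tuple(pts.T)]
    out = np.zeros(fg.shape)
    for i, j in pts:
        d2 = (pts[:, 0] - i) ** 2 + (pts[:, 1] - j) ** 2
        out[i, j] = 2.0 * rho[d2 <= rho * rho + 1e-9].max()
    return out


def _as_skeleton(mask):
    """Treat an already-thin mask as the skeleton itself."""
    from vastile.io_tiling import BinaryMask

    return BinaryMask(mask.pixels, mask.calibration_um_per_px, semantics="skeleton")


def line_mask(shape, pts):
    a = np.zeros(shape, bool)
    for i, j in pts:
        a[i, j] = True
    return a


class TestTissueGate:
    def test_empty_tissue_is_skip_signal(self):
        v = make_mask(np.ones((8, 8), bool))
        t = make_mask(np.zeros((8, 8), bool), semantics="tissue")
        assert apply_tissue_gate(v, t) is None

    def test_vascular_subset_unchanged(self, rng):
        t = make_mask(rng.random((20, 20)) > 0.3, semantics="tissue")
        v = make_mask(t.pixels & (rng.random((20, 20)) > 0.5))
        out = apply_tissue_gate(v, t)
        np.testing.assert_array_equal(out.pixels, v.pixels)

    def test_vessels_outside_tissue_removed(self):
        t = np.zeros((10, 10), bool)
        t[:, :5] = True
        v = np.ones((10, 10), bool)
        out = apply_tissue_gate(make_mask(v), make_mask(t, semantics="tissue"))
        assert not out.pixels[:, 5:].any() and out.pixels[:, :5].all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_tissue_gate(make_mask(np.ones((4, 4), bool)), make_mask(np.ones((5, 4), bool)))


class TestFillSmallHoles:
    def _disk(self, r=15, pad=5):
        n = 2 * (r + pad) + 1
        ii, jj = np.mgrid[0:n, 0:n]
        c = r + pad
        return (ii - c) ** 2 + (jj - c) ** 2 <= r * r

    def test_radius_zero_is_identity(self):
        m = make_mask(self._disk())
        out = fill_small_holes(m, 0.0)
        np.testing.assert_array_equal(out.pixels, m.pixels)

    def test_hole_free_mask_unchanged(self):
        m = make_mask(self._disk())
        out = fill_small_holes(m, 3.0)
        np.testing.assert_array_equal(out.pixels, m.pixels)

    def test_small_enclosed_hole_filled(self):
        d = self._disk(r=15)
        d[19:21, 20] = False  # 2-px hole, equivalent diameter ~1.6 px
        out = fill_small_holes(make_mask(d), 3.0)
        assert out.pixels[19:21, 20].all()

    def test_large_enclosed_hole_preserved(self):
        d = self._disk(r=25, pad=5)
        ii, jj = np.mgrid[0 : d.shape[0], 0 : d.shape[1]]
        hole = (ii - 30) ** 2 + (jj - 30) ** 2 <= 10 * 10  # 20-px diameter
        d &= ~hole
        out = fill_small_holes(make_mask(d), 3.0)
        assert not out.pixels[30, 30]
        # hole may be rounded at its rim by the closing, but its bulk survives
        assert (~out.pixels & hole).sum() >= 0.6 * hole.sum()


class TestLocalThickness:
    def test_matches_bruteforce_on_random_masks(self, rng):
        worst = 0.0
        for _ in range(50):
            shape = tuple(rng.integers(16, 65, 2))
            fg = ndimage.binary_closing(rng.random(shape) < 0.45, np.ones((3, 3)))
            got = local_thickness(make_mask(fg)).values
            want = brute_force_thickness_px(fg)
            if fg.any():
                worst = max(worst, np.abs(got - want)[fg].max())
            assert not got[~fg].any()
        assert worst <= 1.0

    def test_disk_center_value(self):
        ii, jj = np.mgrid[0:41, 0:41]
        d = (ii - 20) ** 2 + (jj - 20) ** 2 <= 100  # radius 10 px
        tm = local_thickness(make_mask(d, cal=1.0))
        assert abs(tm.values[20, 20] - 20.0) <= 1.0

    def test_rectangle_axis_value(self):
        m = np.zeros((30, 120), bool)
        m[10:20, 10:110] = True  # 100 x 10 px
        tm = local_thickness(make_mask(m))
        mid = tm.values[14:16, 60]
        assert np.allclose(mid, 10.0, atol=1.0)

    def test_single_pixel_is_two_px_equivalent(self):
        # pixel-center lattice convention: the smallest disk has radius
        # EDT = 1, hence diameter 2 (documented)
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert local_thickness(make_mask(m)).values[4, 4] == 2.0

    def test_empty_mask_gives_zero_map(self):
        tm = local_thickness(make_mask(np.zeros((5, 5), bool)))
        assert not tm.values.any()

    def test_calibration_scales_values(self):
        m = np.zeros((20, 40), bool)
        m[8:12, 5:35] = True
        a = local_thickness(make_mask(m, cal=1.0)).values
        b = local_thickness(make_mask(m, cal=2.0)).values
        np.testing.assert_allclose(b, 2.0 * a)


class TestSkeletonize:
    def test_empty_in_empty_out(self):
        assert not skeletonize(make_mask(np.zeros((6, 6), bool))).pixels.any()

    def test_rectangle_skeleton_is_single_open_curve(self):
        m = np.zeros((30, 120), bool)
        m[10:20, 10:110] = True
        sk = skeletonize(make_mask(m))
        g = build_skeleton_graph(sk, constant_thickness(m, 10.0))
        assert g.n_clusters == 1
        assert g.n_endpoints == 2 and g.n_junctions == 0

    def test_plus_shape_has_four_endpoints_one_junction(self):
        m = np.zeros((100, 100), bool)
        m[46:54, 20:80] = True
        m[20:80, 46:54] = True
        cfg = PipelineConfig(calibration_um_per_px=1.0, prune_threshold_um=6.0, close_radius_um=0.0)
        mask = make_mask(m)
        thick = local_thickness(mask)
        g = build_skeleton_graph(skeletonize(mask), thick)
        g = prune_short_end_branches(g, cfg.prune_threshold_um)
        assert g.n_endpoints == 4
        assert g.n_junctions == 1
        assert g.n_clusters == 1


class TestSkeletonGraph:
    def test_horizontal_line(self):
        pts = [(5, j) for j in range(3, 14)]  # 11 px
        g = build_skeleton_graph(
            _as_skeleton(make_mask(line_mask((10, 20), pts))),
            constant_thickness(line_mask((10, 20), pts)),
        )
        assert g.n_branches == 1 and g.n_endpoints == 2 and g.n_junctions == 0
        b = g.branches[0]
        assert b.length_um == pytest.approx(10.0)
        assert b.euclidean_um == pytest.approx(10.0)
        assert b.tortuosity == pytest.approx(1.0)

    def test_diagonal_line_length_is_10_root_2(self):
        pts = [(3 + k, 3 + k) for k in range(11)]
        g = build_skeleton_graph(
            _as_skeleton(make_mask(line_mask((20, 20), pts))),
            constant_thickness(line_mask((20, 20), pts)),
        )
        b = g.branches[0]
        assert b.length_um == pytest.approx(10.0 * math.sqrt(2.0))
        assert b.tortuosity == pytest.approx(1.0)

    def test_chamfer_option_agrees_on_axis_and_diagonal(self):
        pts = [(3 + k, 3 + k) for k in range(11)]
        arr = line_mask((20, 20), pts)
        g = build_skeleton_graph(
            _as_skeleton(make_mask(arr)), constant_thickness(arr), length_method="chamfer"
        )
        assert g.branches[0].length_um == pytest.approx(10.0 * math.sqrt(2.0))

    def _y_shape(self, arm=20, stub=None):
        # center at (40, 40): one arm up, two arms down-diagonal
        shape = (80, 80)
        pts = set()
        for k in range(1, arm + 1):
            pts.add((40 - k, 40))
            pts.add((40 + k, 40 - k))
        n_stub = stub if stub is not None else arm
        for k in range(1, n_stub + 1):
            pts.add((40 + k, 40 + k))
        pts.add((40, 40))
        return line_mask(shape, pts)

    def test_y_shape_three_branches_one_junction(self):
        arr = self._y_shape()
        g = build_skeleton_graph(_as_skeleton(make_mask(arr)), constant_thickness(arr))
        assert g.n_branches == 3
        assert g.n_junctions == 1
        assert g.n_endpoints == 3
        assert g.n_clusters == 1

    def test_tortuosity_is_length_over_euclidean_for_every_branch(self):
        _, _, vasc, _ = generate_network(
            4, tortuosity_mode="random-walk", noise_sd=0.0, seed=11, image_shape=(300, 300)
        )
        thick = local_thickness(vasc)
        g = build_skeleton_graph(skeletonize(vasc), thick)
        assert g.n_branches >= 1
        for b in g.branches:
            if not b.is_loop:
                assert b.tortuosity == pytest.approx(b.length_um / b.euclidean_um)
            assert b.area_um2 == pytest.approx(b.mean_diameter_um * b.length_um)
            assert b.length_um >= b.euclidean_um - 1e-9

    def test_arc_chord_arithmetic(self):
        # a branch of length 30 µm with endpoints 25 µm apart has T = 1.2
        b = BranchRecord(
            pixel_path=np.zeros((2, 2), int),
            length_um=30.0,
            euclidean_um=25.0,
            mean_diameter_um=5.0,
            tortuosity=30.0 / 25.0,
            area_um2=150.0,
            end_types=("endpoint", "endpoint"),
        )
        assert b.tortuosity == pytest.approx(1.2)

    def test_isolated_pixel_is_cluster_without_branch(self):
        arr = np.zeros((9, 9), bool)
        arr[4, 4] = True
        g = build_skeleton_graph(_as_skeleton(make_mask(arr)), constant_thickness(arr))
        assert g.n_branches == 0 and g.n_clusters == 1

    def test_closed_ring_is_single_loop_branch(self):
        ii, jj = np.mgrid[0:31, 0:31]
        r = np.hypot(ii - 15, jj - 15)
        ring = (r >= 9.5) & (r <= 10.5)
        from skimage.morphology import skeletonize as sk

        thin = sk(ring)
        g = build_skeleton_graph(_as_skeleton(make_mask(thin)), constant_thickness(thin))
        assert g.n_branches == 1
        assert g.branches[0].is_loop
        assert g.n_endpoints == 0 and g.n_junctions == 0 and g.n_clusters == 1

    def test_zero_thickness_under_skeleton_is_an_error(self):
        pts = [(2, j) for j in range(2, 8)]
        arr = line_mask((5, 10), pts)
        with pytest.raises(RuntimeError):
            build_skeleton_graph(_as_skeleton(make_mask(arr)), constant_thickness(np.zeros((5, 10))))


class TestPruning:
    def test_threshold_zero_is_identity(self):
        arr = TestSkeletonGraph()._y_shape(stub=3)
        g = build_skeleton_graph(_as_skeleton(make_mask(arr)), constant_thickness(arr))
        pruned = prune_short_end_branches(g, 0.0)
        assert pruned.n_branches == g.n_branches
        assert pruned.n_endpoints == g.n_endpoints

    def test_short_stub_pruned_and_junction_merged(self):
        # Y with arms 20, 20 and a 3-px stub; threshold 5 µm removes the
        # stub and merges the remaining two arms into one branch
        arr = TestSkeletonGraph()._y_shape(arm=20, stub=3)
        g = build_skeleton_graph(_as_skeleton(make_mask(arr)), constant_thickness(arr))
        assert g.n_branches == 3
        pruned = prune_short_end_branches(g, 5.0)
        assert pruned.n_branches == 1
        assert pruned.n_endpoints == 2
        assert pruned.n_junctions == 0
        assert pruned.n_clusters == 1
        both = sorted(b.length_um for b in g.branches)[1:]
        assert pruned.branches[0].length_um == pytest.approx(sum(both))

    def test_all_branches_long_enough_unchanged(self):
        arr = TestSkeletonGraph()._y_shape(arm=20)
        g = build_skeleton_graph(_as_skeleton(make_mask(arr)), constant_thickness(arr))
        pruned = prune_short_end_branches(g, 5.0)
        assert pruned.n_branches == 3 and pruned.n_junctions == 1

    def test_merged_diameter_is_length_weighted(self):
        arr = TestSkeletonGraph()._y_shape(arm=20, stub=3)
        thick = constant_thickness(arr, 4.0)
        g = build_skeleton_graph(_as_skeleton(make_mask(arr)), thick)
        pruned = prune_short_end_branches(g, 5.0)
        assert pruned.branches[0].mean_diameter_um == pytest.approx(4.0)

    @pytest.mark.parametrize("mode", ["straight", "sinusoid"])
    def test_monotone_in_threshold(self, mode):
        _, _, vasc, _ = generate_network(
            5, tortuosity_mode=mode, noise_sd=0.0, seed=4, image_shape=(320, 320)
        )
        thick = local_thickness(vasc)
        g = build_skeleton_graph(skeletonize(vasc), thick)
        prev_b, prev_e = np.inf, np.inf
        for thr in (0.0, 2.0, 5.0, 10.0, 20.0):
            p = prune_short_end_branches(g, thr)
            assert p.n_branches <= prev_b
            assert p.n_endpoints <= prev_e
            prev_b, prev_e = p.n_branches, p.n_endpoints


class TestCompartments:
    def _graph_with_diameters(self, diams):
        branches = [
            BranchRecord(
                pixel_path=np.array([[0, 0], [0, 10]]),
                length_um=10.0,
                euclidean_um=10.0,
                mean_diameter_um=float(d),
                tortuosity=1.0,
                area_um2=10.0 * d,
                end_types=("endpoint", "endpoint"),
                end_nodes=(("E", (0, 0)), ("E", (0, 10))),
            )
            for d in diams
        ]
        return SkeletonGraph(branches, 0, 2 * len(diams), len(diams), 1.0)

    def test_split_by_mean_diameter(self):
        g = self._graph_with_diameters([4.0, 20.0])
        above, below = split_compartments(g, 10.0)
        assert [b.mean_diameter_um for b in above.branches] == [20.0]
        assert [b.mean_diameter_um for b in below.branches] == [4.0]

    def test_all_below_leaves_above_empty(self):
        above, below = split_compartments(self._graph_with_diameters([2.0, 3.0]), 10.0)
        assert above.n_branches == 0 and below.n_branches == 2

    def test_tie_goes_above(self):
        above, _ = split_compartments(self._graph_with_diameters([10.0]), 10.0)
        assert above.n_branches == 1

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        g = self._graph_with_diameters(rng.uniform(1, 25, 40))
        above, below = split_compartments(g, 10.0)
        assert above.n_branches + below.n_branches == g.n_branches
        ids = {id(b) for b in above.branches} | {id(b) for b in below.branches}
        assert len(ids) == g.n_branches


class TestTileReadouts:
    cfg = PipelineConfig(calibration_um_per_px=1.0, separation_threshold_um=10.0)

    def _single_tube_graph(self):
        b = BranchRecord(
            pixel_path=np.array([[0, 0], [0, 100]]),
            length_um=100.0,
            euclidean_um=100.0,
            mean_diameter_um=8.0,
            tortuosity=1.0,
            area_um2=800.0,
            end_types=("endpoint", "endpoint"),
            end_nodes=(("E", (0, 0)), ("E", (0, 100))),
        )
        return SkeletonGraph([b], 0, 2, 1, 1.0)

    def test_single_tube_formulas(self):
        g = self._single_tube_graph()
        above, below = split_compartments(g, 10.0)
        # 0.1 mm² of tissue = 100,000 px at 1 µm/px
        r = compute_tile_readouts(g, above, below, 100_000, self.cfg)
        assert r.all.vascular_density_pct == pytest.approx(0.8)
        assert r.all.vessel_length_density_mm_per_mm2 == pytest.approx(1.0)
        assert r.all.branch_density_per_mm2 == pytest.approx(10.0)
        assert r.all.mean_vessel_diameter_um == pytest.approx(8.0)
        assert r.tissue_area_mm2 == pytest.approx(0.1)

    def test_empty_graph_densities_zero_means_missing(self):
        g = SkeletonGraph([], 0, 0, 0, 1.0)
        above, below = split_compartments(g, 10.0)
        r = compute_tile_readouts(g, above, below, 10_000, self.cfg)
        assert r.all.vascular_density_pct == 0.0
        assert r.all.vessel_length_density_mm_per_mm2 == 0.0
        assert math.isnan(r.all.mean_vessel_diameter_um)
        assert math.isnan(r.all.tortuosity_index)

    def test_zero_tissue_area_is_an_error(self):
        g = self._single_tube_graph()
        above, below = split_compartments(g, 10.0)
        with pytest.raises(ValueError):
            compute_tile_readouts(g, above, below, 0, self.cfg)

    def test_compartment_additivity_is_exact(self, rng):
        _, tissue, vasc, _ = generate_network(
            6, widths=[4, 8, 16], noise_sd=0.0, seed=9, image_shape=(360, 360)
        )
        cfg = PipelineConfig(calibration_um_per_px=1.0, prune_threshold_um=6.0)
        r = quantify_mask(vasc, tissue.area_px(), cfg)
        assert r.above.total_length_um + r.below.total_length_um == pytest.approx(
            r.all.total_length_um, rel=1e-12
        )
        assert r.above.total_area_um2 + r.below.total_area_um2 == pytest.approx(
            r.all.total_area_um2, rel=1e-12
        )
        assert r.above.n_branches + r.below.n_branches == r.all.n_branches
        assert (
            r.above.vessel_length_density_mm_per_mm2 + r.below.vessel_length_density_mm_per_mm2
            == pytest.approx(r.all.vessel_length_density_mm_per_mm2, rel=1e-12)
        )

    def test_density_capped_at_100(self):
        b = BranchRecord(
            pixel_path=np.array([[0, 0], [0, 100]]),
            length_um=1000.0,
            euclidean_um=1000.0,
            mean_diameter_um=50.0,
            tortuosity=1.0,
            area_um2=50_000.0,
            end_types=("endpoint", "endpoint"),
            end_nodes=(("E", (0, 0)), ("E", (0, 100))),
        )
        g = SkeletonGraph([b], 0, 2, 1, 1.0)
        above, below = split_compartments(g, 10.0)
        r = compute_tile_readouts(g, above, below, 100, self.cfg)
        assert r.all.vascular_density_pct == 100.0
        assert r.all.vascular_density_raw_pct > 100.0


class TestScaleEquivariance:
    def test_doubling_calibration(self):
        arr = np.zeros((80, 200), bool)
        arr[36:44, 20:180] = True
        cfg1 = PipelineConfig(calibration_um_per_px=1.0, prune_threshold_um=4.0)
        cfg2 = PipelineConfig(
            calibration_um_per_px=2.0, prune_threshold_um=8.0, separation_threshold_um=20.0
        )
        r1 = quantify_mask(make_mask(arr, cal=1.0), int(arr.size), cfg1)
        r2 = quantify_mask(make_mask(arr, cal=2.0), int(arr.size), cfg2)
        assert r2.all.mean_vessel_diameter_um == pytest.approx(2 * r1.all.mean_vessel_diameter_um)
        assert r2.all.mean_branch_length_um == pytest.approx(2 * r1.all.mean_branch_length_um)
        assert r2.all.tortuosity_index == pytest.approx(r1.all.tortuosity_index)
        assert r2.all.n_branches == r1.all.n_branches
        # area denominator quadruples while Σ(d̄·L) quadruples too:
        # the density estimate is scale-free
        assert r2.all.vascular_density_pct == pytest.approx(r1.all.vascular_density_pct)
        assert r2.all.vessel_length_density_mm_per_mm2 == pytest.approx(
            r1.all.vessel_length_density_mm_per_mm2 / 2
        )
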