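"""Heterogeneity (PC/PD/PV), vessel-graph morphometrics, functional
metrics, sentinel extraction and the longitudinal arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parm import metrics
from parm.clustering import PatternModel
from parm.reconstruction import SuperResolvedMap
from parm.trail import FeaturePointSet


def _model(centers, occupancy):
    centers = np.asarray(centers, dtype=float)
    occupancy = np.asarray(occupancy, dtype=int)
    labels = np.concatenate([np.full(m, i + 1) for i, m in enumerate(occupancy)])
    return PatternModel(K=len(occupancy), centers=centers, labels=labels,
                        occupancy=occupancy)


def _points(speed, direction):
    n = len(speed)
    return FeaturePointSet(
        t_index=np.zeros(n, dtype=int), x=np.zeros(n), z=np.zeros(n),
        speed=np.asarray(speed, dtype=float),
        direction=np.asarray(direction, dtype=float),
        coherence=np.ones(n), intensity=np.ones(n),
        clipped=np.zeros(n, dtype=bool))


def _map_from_mask(mask, pixel_size=0.05):
    return SuperResolvedMap(grid=mask.astype(float), pattern_index=1,
                            pixel_size=pixel_size)


class TestHeterogeneity:
    def test_pd_is_max_pairwise_distance(self):
        h = metrics.heterogeneity(_model([[0, 0, 0], [3, 4, 0]], [10, 10]))
        assert h.PC == 2
        assert h.PD == pytest.approx(5.0)

    def test_equal_occupancy_zero_pv(self):
        h = metrics.heterogeneity(_model([[0, 0, 0], [1, 0, 0]], [50, 50]))
        np.testing.assert_allclose(h.ratios, [0.5, 0.5])
        assert h.PV == 0.0

    def test_unbalanced_occupancy_sample_variance(self):
        # R = (0.9, 0.05, 0.05); sample variance (divisor K-1) = 0.240833...
        h = metrics.heterogeneity(
            _model([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [90, 5, 5]))
        np.testing.assert_allclose(h.ratios, [0.9, 0.05, 0.05])
        assert h.PV == pytest.approx(0.2408333333, abs=1e-9)

    def test_population_divisor_option(self):
        h = metrics.heterogeneity(
            _model([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [90, 5, 5]), ddof=0)
        assert h.PV == pytest.approx(np.var([0.9, 0.05, 0.05]))

    def test_single_pattern_conventions(self):
        h = metrics.heterogeneity(_model([[0.2, 0.3, 0.1]], [77]))
        assert (h.PC, h.PD, h.PV) == (1, 0.0, 0.0)

    def test_pd_invariant_to_relabeling_and_isometry(self, rng):
        centers = rng.random((4, 3))
        occ = [10, 20, 30, 40]
        h = metrics.heterogeneity(_model(centers, occ))
        perm = rng.permutation(4)
        h_perm = metrics.heterogeneity(_model(centers[perm],
                                              np.asarray(occ)[perm]))
        assert h.PD == pytest.approx(h_perm.PD)
        assert h.PV == pytest.approx(h_perm.PV)
        # isometry: rotation + translation preserves PD
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        h_iso = metrics.heterogeneity(_model(centers @ rot.T + 5.0, occ))
        assert h_iso.PD == pytest.approx(h.PD)

    @pytest.mark.parametrize("k", [2, 3])
    def test_pv_maximal_when_one_ratio_dominates(self, k):
        # exhaustive grid over occupancy proportions: PV is maximal at the
        # most lopsided distribution and 0 only at the uniform one
        total = 60
        best_pv, best_occ = -1.0, None
        centers = np.eye(3)[:k]
        for occ in itertools.combinations_with_replacement(range(1, total), k):
            if sum(occ) != total:
                continue
            for perm in set(itertools.permutations(occ)):
                pv = metrics.heterogeneity(
                    _model(centers, list(perm))).PV
                if pv > best_pv:
                    best_pv, best_occ = pv, perm
        assert max(best_occ) == total - (k - 1)
        uniform = metrics.heterogeneity(_model(centers, [total // k] * k)).PV
        assert uniform == pytest.approx(0.0)


class TestVesselGraph:
    def test_straight_vessel_one_branch_no_nodes(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 5:35] = True
        g = metrics.build_vessel_graph(_map_from_mask(mask), threshold=0.5,
                                       min_object_size=1)
        assert len(g.nodes) == 0
        assert len(g.branches) == 1

    def test_y_phantom_one_node_three_branches(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[30, 10:31] = True                 # stem
        for i in range(20):
            mask[30 - i, 30 + i] = True        # upper arm
            mask[30 + i, 30 + i] = True        # lower arm
        g = metrics.build_vessel_graph(_map_from_mask(mask), threshold=0.5,
                                       min_object_size=1)
        assert len(g.nodes) == 1
        assert len(g.branches) == 3

    def test_x_phantom_matches_pixel_graph_oracle(self):
        mask = np.zeros((61, 61), dtype=bool)
        for i in range(61):
            mask[i, i] = True
            mask[i, 60 - i] = True
        g = metrics.build_vessel_graph(_map_from_mask(mask), threshold=0.5,
                                       min_object_size=1)
        # brute-force oracle on the skeleton pixel graph
        skel = g.skeleton
        pix = set(zip(*map(list, np.nonzero(skel))))
        deg = {p: sum((p[0] + dz, p[1] + dx) in pix
                      for dz in (-1, 0, 1) for dx in (-1, 0, 1)
                      if (dz, dx) != (0, 0)) for p in pix}
        junctions = {p for p, d in deg.items() if d >= 3}
        # cluster touching junction pixels
        from scipy import ndimage as ndi
        jm = np.zeros_like(skel)
        for p in junctions:
            jm[p] = True
        _, n_junc = ndi.label(jm, structure=np.ones((3, 3)))
        body = skel & ~jm
        _, n_branch = ndi.label(body, structure=np.ones((3, 3)))
        assert len(g.nodes) == n_junc
        assert len(g.branches) == n_branch

    def test_empty_map_empty_graph(self):
        g = metrics.build_vessel_graph(
            _map_from_mask(np.zeros((30, 30), dtype=bool)))
        s = metrics.structural_metrics(g)
        assert (s.VD, s.VN, s.NN) == (0.0, 0, 0)


class TestStructuralMetrics:
    def test_straight_vessel_vt_exactly_one(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 5:35] = True
        g = metrics.build_vessel_graph(_map_from_mask(mask), threshold=0.5,
                                       min_object_size=1)
        assert metrics.structural_metrics(g).VT == pytest.approx(1.0)

    def test_semicircle_vt_is_half_pi(self):
        # arc/chord of a half circle = (pi r)/(2 r) = pi/2, within 5%
        r, c = 40, (10, 50)
        mask = np.zeros((60, 100), dtype=bool)
        for theta in np.linspace(0, np.pi, 2000):
            z = int(round(c[0] + r * np.sin(theta)))
            x = int(round(c[1] + r * np.cos(theta)))
            mask[z, x] = True
        g = metrics.build_vessel_graph(_map_from_mask(mask), threshold=0.5,
                                       min_object_size=1)
        vt = metrics.structural_metrics(g).VT
        assert vt == pytest.approx(np.pi / 2, rel=0.05)

    def test_full_frame_mask_vd_one(self):
        mask = np.ones((30, 30), dtype=bool)
        g = metrics.build_vessel_graph(_map_from_mask(mask), threshold=0.5,
                                       min_object_size=1)
        assert metrics.structural_metrics(g).VD == pytest.approx(1.0)

    def test_metrics_consistent_under_roi_cropping(self):
        # recomputing on a sub-ROI equals metrics of the cropped map
        rng = np.random.default_rng(3)
        mask = np.zeros((80, 80), dtype=bool)
        mask[20, 5:75] = True
        mask[50, 5:75] = True
        crop = mask[:40]
        m_full = SuperResolvedMap(grid=mask.astype(float), pattern_index=1,
                                  pixel_size=0.05)
        m_crop = SuperResolvedMap(grid=crop.astype(float), pattern_index=1,
                                  pixel_size=0.05)
        roi = np.zeros_like(mask)
        roi[:40] = True
        g_roi = metrics.build_vessel_graph(m_full, threshold=0.5,
                                           min_object_size=1, roi_mask=roi)
        g_crop = metrics.build_vessel_graph(m_crop, threshold=0.5,
                                            min_object_size=1)
        s_roi = metrics.structural_metrics(g_roi)
        s_crop = metrics.structural_metrics(g_crop)
        assert s_roi.VD == pytest.approx(s_crop.VD)
        assert s_roi.VN == s_crop.VN
        assert s_roi.NN == s_crop.NN
        assert s_roi.VNP == pytest.approx(s_crop.VNP)


class TestFunctionalMetrics:
    def test_constant_speed_zero_entropy(self):
        f = metrics.functional_metrics(_points([3.0] * 50, [0.1] * 50))
        assert f.SE == 0.0
        assert f.MS == pytest.approx(3.0)

    def test_uniform_over_16_bins_gives_4_bits(self):
        # one sample centered in each of 16 equal bins
        speed = (np.arange(16) + 0.5) * (8.0 / 16)
        f = metrics.functional_metrics(_points(speed, np.zeros(16)),
                                       speed_bins=16, v_max=8.0)
        assert f.SE == pytest.approx(4.0)

    def test_uniform_directions_high_circular_variance(self, rng):
        n = 4000
        d = rng.uniform(-np.pi, np.pi, n)
        f = metrics.functional_metrics(_points(np.ones(n), d))
        assert abs(f.OV - 1.0) < 3 / np.sqrt(n)

    def test_aligned_directions_zero_variance(self):
        f = metrics.functional_metrics(_points([1, 2, 3], [0.5, 0.5, 0.5]))
        assert f.OV == pytest.approx(0.0, abs=1e-12)

    def test_single_point_conventions(self):
        f = metrics.functional_metrics(_points([2.0], [1.0]))
        assert f.SE == 0.0
        assert f.OV == pytest.approx(0.0, abs=1e-12)


class TestSentinelSplit:
    def _maps(self, k, shape=(20, 20)):
        out = []
        for i in range(k):
            grid = np.zeros(shape)
            grid[2 * i + 1, :] = 1.0
            out.append(SuperResolvedMap(grid=grid, pattern_index=i + 1,
                                        pixel_size=0.05))
        return out

    def test_fastest_pattern_is_sentinel(self):
        model = _model([[0, 1, 0], [1, -1, 0]], [30, 30])
        pts = _points([2.0] * 30 + [8.0] * 30, [0.0] * 60)
        split = metrics.sentinel_split(model, self._maps(2), pts)
        assert split.sentinel_index == 2
        np.testing.assert_allclose(split.mean_speeds, [2.0, 8.0])
        np.testing.assert_allclose(split.non_sentinel_map.grid,
                                   self._maps(2)[0].grid)

    def test_k1_sentinel_is_whole_map(self):
        model = _model([[0.5, 0.5, 0.5]], [40])
        pts = _points([3.0] * 40, [0.0] * 40)
        split = metrics.sentinel_split(model, self._maps(1), pts)
        assert split.sentinel_index == 1
        assert not split.non_sentinel_map.grid.any()

    def test_tie_warns_and_takes_lowest_index(self):
        model = _model([[0, 1, 0], [1, -1, 0]], [30, 30])
        pts = _points([5.0] * 60, [0.0] * 60)
        with pytest.warns(UserWarning, match="tie"):
            split = metrics.sentinel_split(model, self._maps(2), pts)
        assert split.sentinel_index == 1


class TestLongitudinal:
    def test_volume_of_6mm_tumor_near_100mm3(self):
        # a = b = 6 mm -> 108 mm^3, matching the ~100 mm^3 baseline tumors
        assert metrics.tumor_volume(6.0, 6.0) == pytest.approx(108.0)

    def test_volume_requires_long_axis_first(self):
        with pytest.raises(ValueError):
            metrics.tumor_volume(4.0, 6.0)

    def test_pd_relative_change_59_percent(self):
        assert metrics.relative_change(2.46, 1.55) \
            == pytest.approx(0.587, abs=0.001)

    def test_pv_relative_change_65_percent(self):
        assert metrics.relative_change(0.91, 0.55) \
            == pytest.approx(0.6545, abs=0.001)

    def test_delta_v_both_conventions(self):
        assert metrics.delta_v(100.0, 200.0) == pytest.approx(-0.5)
        assert metrics.delta_v(100.0, 200.0, baseline_first=False) \
            == pytest.approx(1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            metrics.relative_change(1.0, 0.0)

    def test_measurement_dataclass(self):
        m = metrics.TumorMeasurement(a=8.0, b=5.0, day=14)
        assert m.V == pytest.approx(100.0)


class TestSpearman:
    def test_monotone_is_one(self):
        assert metrics.spearman([1, 2, 3, 4], [10, 20, 30, 40]) \
            == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert metrics.spearman([1, 2, 3, 4], [4, 3, 2, 1]) \
            == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_formula(self):
        xs = [1, 2, 3, 4, 5]
        ys = [2, 1, 4, 3, 5]
        # no ties: rho = 1 - 6 sum(d^2) / (n (n^2-1))
        rx = np.argsort(np.argsort(xs))
        ry = np.argsort(np.argsort(ys))
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (5 * 24)
        assert metrics.spearman(xs, ys) == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            metrics.spearman([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20,
                    unique=True))
    def test_bounded_and_symmetric(self, xs):
        ys = list(reversed(xs))
        r = metrics.spearman(xs, ys)
        assert -1.0 <= r <= 1.0
        assert metrics.spearman(ys, xs) == pytest.approx(r)
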