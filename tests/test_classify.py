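from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lgquant import (ClassificationParams, DegenerateDataError,
                     MeasurementError, MultiChannelVolume, NucleusDetection,
                     RoiMask, ValidationError, analyze_specimen,
                     classify_positive, count_positive_cells,
                     differentiation_index, measure_marker)
from lgquant.experiments import count_scene_params
from lgquant.synthetic import NoiseModel, match_detections, render_scene, sample_scene

from oracles import otsu_sweep, sphere_mean_exhaustive


def _det(label, center, radius=2.0):
    return NucleusDetection(label, center, 100, radius)


def _vol(grid, spacing=(1.0, 1.0, 1.0), name="marker"):
    return MultiChannelVolume({name: grid}, spacing=spacing)


class TestMeasureMarker:
    def test_uniform_channel_gives_uniform_means(self):
        vol = _vol(np.full((8, 8, 8), 3.25))
        dets = [_det(1, (4.0, 4.0, 4.0)), _det(2, (2.0, 5.0, 6.0))]
        out = measure_marker(dets, vol, "marker", 2.0)
        assert out == [(1, pytest.approx(3.25)), (2, pytest.approx(3.25))]

    def test_sphere_of_one_voxel_returns_that_voxel(self, rng):
        grid = rng.random((8, 8, 8))
        vol = _vol(grid)
        dets = [_det(1, (3.0, 4.0, 5.0))]
        params = ClassificationParams(radius_factor=0.2)  # 0.2 * 2 µm < 1 voxel
        (pair,) = measure_marker(dets, vol, "marker", 2.0, params)
        assert pair[1] == pytest.approx(grid[3, 4, 5])

    def test_matches_exhaustive_voxel_scan(self, rng):
        """Sphere means agree with a brute-force scan of every voxel,
        including anisotropic spacing and border clipping."""
        spacing = (1.0, 0.5, 0.5)
        grid = rng.random((10, 16, 16))
        vol = _vol(grid, spacing)
        centers = [(4.7, 3.1, 5.9), (0.5, 0.5, 0.5), (9.0, 7.6, 7.4)]
        dets = [_det(i, c) for i, c in enumerate(centers)]
        out = measure_marker(dets, vol, "marker", 2.0,
                             ClassificationParams(radius_factor=1.5))
        for (label, mean), center in zip(out, centers):
            expected, n = sphere_mean_exhaustive(grid, spacing, center, 3.0)
            assert n > 0
            assert mean == pytest.approx(expected, abs=1e-9)

    def test_empty_sphere_is_a_measurement_error(self):
        vol = _vol(np.ones((4, 4, 4)), spacing=(10.0, 10.0, 10.0))
        dets = [_det(7, (5.0, 5.0, 5.0))]
        with pytest.raises(MeasurementError, match="nucleus 7"):
            measure_marker(dets, vol, "marker", 0.3)


class TestClassify:
    def test_absolute_threshold_with_no_qualifying_cells(self):
        meas = {"m": [(1, 2.0), (2, 3.0)]}
        calls, thr = classify_positive(meas, ClassificationParams(threshold="absolute:10"))
        assert not any(c.positive for c in calls)
        assert count_positive_cells(calls, "m") == 0

    def test_otsu_splits_bimodal_means_like_exhaustive_sweep(self, rng):
        means = np.concatenate([10 + rng.normal(0, 0.5, 7),
                                100 + rng.normal(0, 5, 3)])
        order = rng.permutation(10)
        meas = {"m": [(int(i), float(means[i])) for i in order]}
        calls, _ = classify_positive(meas)
        positive = {c.label for c in calls if c.positive}
        assert positive == otsu_sweep(means)
        assert count_positive_cells(calls, "m") == 3

    def test_ties_at_threshold_count_positive(self):
        meas = {"m": [(1, 5.0), (2, 4.0)]}
        calls, _ = classify_positive(meas, ClassificationParams(threshold="absolute:5"))
        assert [c.positive for c in calls] == [True, False]

    def test_constant_means_under_otsu_are_degenerate(self):
        with pytest.raises(DegenerateDataError, match="absolute"):
            classify_positive({"m": [(1, 2.0), (2, 2.0)]})

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
           st.floats(0, 100), st.floats(0, 100))
    def test_raising_absolute_threshold_never_adds_positives(self, means, t1, t2):
        lo, hi = sorted((t1, t2))
        meas = {"m": [(i, v) for i, v in enumerate(means)]}
        n_lo = count_positive_cells(
            classify_positive(meas, ClassificationParams(threshold=f"absolute:{lo}"))[0], "m")
        n_hi = count_positive_cells(
            classify_positive(meas, ClassificationParams(threshold=f"absolute:{hi}"))[0], "m")
        assert n_hi <= n_lo

    def test_channels_are_independent(self, rng):
        """Perturbing channel B leaves the sphere means of channel A alone."""
        ga, gb = rng.random((6, 12, 12)), rng.random((6, 12, 12))
        dets = [_det(1, (3.0, 6.0, 6.0))]
        vol1 = MultiChannelVolume({"A": ga, "B": gb})
        vol2 = MultiChannelVolume({"A": ga, "B": gb * 9 + 1})
        m1 = measure_marker(dets, vol1, "A", 2.0)
        m2 = measure_marker(dets, vol2, "A", 2.0)
        assert m1 == m2


class TestDifferentiationIndex:
    def _calls(self, n, positives, marker="m"):
        from lgquant import CellClassification
        return [CellClassification(i, marker, 10.0 if i in positives else 1.0,
                                   i in positives) for i in range(n)]

    def _dets(self, n):
        return [_det(i, (float(i), 1.0, 1.0)) for i in range(n)]

    def test_nine_of_thirty_gives_exact_three_tenths(self):
        report = differentiation_index(self._calls(30, set(range(9))), self._dets(30))
        assert report.index_exact["m"] == Fraction(3, 10)
        assert report.index["m"] == pytest.approx(0.3)
        assert report.positives["m"] == 9 and report.total_cells == 30

    def test_bounds_all_and_none(self):
        all_pos = differentiation_index(self._calls(5, set(range(5))), self._dets(5))
        none = differentiation_index(self._calls(5, set()), self._dets(5))
        assert all_pos.index["m"] == 1.0 and none.index["m"] == 0.0

    def test_roi_restriction_partitions_consistently(self):
        """Counts over a partition of the grid sum to the unrestricted count."""
        n = 12
        dets = [_det(i, (float(i), 1.0, 1.0)) for i in range(n)]
        calls = self._calls(n, {0, 3, 5, 8, 11})
        left = np.zeros((12, 4, 4), bool)
        left[:6] = True
        roi_l = RoiMask(left, "left")
        roi_r = RoiMask(~left, "right")
        full = differentiation_index(calls, dets)
        part_l = differentiation_index(calls, dets, restrict_to=roi_l, spacing=(1, 1, 1))
        part_r = differentiation_index(calls, dets, restrict_to=roi_r, spacing=(1, 1, 1))
        assert part_l.positives["m"] + part_r.positives["m"] == full.positives["m"]
        assert part_l.total_cells + part_r.total_cells == full.total_cells

    def test_empty_restriction_is_undefined_not_zero(self):
        roi = RoiMask(np.zeros((12, 4, 4), bool), "void")
        roi.voxels[0, 0, 0] = True  # nonempty mask but no centroids inside
        dets = [_det(1, (5.0, 2.0, 2.0))]
        with pytest.raises(DegenerateDataError, match="undefined"):
            differentiation_index(self._calls(2, set()), dets,
                                  restrict_to=roi, spacing=(1, 1, 1))

    def test_unknown_marker_count_is_an_error(self):
        with pytest.raises(ValidationError):
            count_positive_cells(self._calls(3, set()), "nope")


class TestPipelineAccuracy:
    def test_marker_calls_match_ground_truth(self):
        """Full pipeline at default noise: >= 95% of matched cells receive
        the ground-truth positive/negative call."""
        scene = sample_scene(count_scene_params(
            60, markers={"plasmatocyte": 0.3}), 17)
        vol = render_scene(scene, NoiseModel())
        res = analyze_specimen(vol, "dapi", ["plasmatocyte"])
        calls = {c.label: c.positive for c in res.classifications}
        # greedy match detections to truth by distance
        correct = total = 0
        truth = {tuple(np.round(n.center_um, 3)): "plasmatocyte" in n.markers
                 for n in scene.nuclei}
        pts = np.array(list(truth))
        for det in res.detections:
            d = np.linalg.norm(pts - det.centroid_um, axis=1)
            if d.min() <= 2.0:
                total += 1
                if truth[tuple(pts[d.argmin()])] == calls[det.label]:
                    correct += 1
        assert total >= 55
        assert correct / total >= 0.95
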