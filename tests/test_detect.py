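import numpy as np
import pytest
from scipy import ndimage as ndi

from lgquant import (DegenerateDataError, DetectionParams, NucleusDetection,
                     NoiseModel, ThresholdRule, ValidationError, detect_nuclei,
                     dog_filter, estimate_mean_radius, extract_nuclei,
                     make_mask)
from lgquant.experiments import count_recovery, count_scene_params
from lgquant.synthetic import NOISELESS, render_scene, sample_scene

from oracles import flood_fill_components, labels_to_partition

UNIT = (1.0, 1.0, 1.0)


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        vol = np.full((4, 32, 32), 7.3)
        out = dog_filter(vol, UNIT, 1.0, 4.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_linearity_modulo_dc(self, rng):
        vol = rng.random((3, 24, 24))
        base = dog_filter(vol, UNIT, 1.0, 3.0)
        scaled = dog_filter(2.5 * vol + 11.0, UNIT, 1.0, 3.0)
        np.testing.assert_allclose(scaled, 2.5 * base, atol=1e-9)

    def test_gaussian_blob_response_peaks_at_blob_centre(self):
        """A sigma=3 px Gaussian blob filtered with (1, 6): the response
        maximum sits at the centre with the closed-form DoG amplitude
        A * [s_b^2/(s_b^2+s_s^2) - s_b^2/(s_b^2+s_w^2)]."""
        amp, sb = 10.0, 3.0
        yy, xx = np.mgrid[:64, :64]
        img = amp * np.exp(-((yy - 31.0) ** 2 + (xx - 29.0) ** 2) / (2 * sb ** 2))
        out = dog_filter(img[None], UNIT, 1.0, 6.0)[0]
        peak = np.unravel_index(out.argmax(), out.shape)
        assert abs(peak[0] - 31) <= 1 and abs(peak[1] - 29) <= 1
        expected = amp * (sb ** 2 / (sb ** 2 + 1.0) - sb ** 2 / (sb ** 2 + 36.0))
        assert out.max() == pytest.approx(expected, rel=0.02)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValidationError):
            dog_filter(np.zeros((2, 4, 4)), UNIT, 3.0, 1.0)


class TestMakeMask:
    def test_absolute_threshold_above_max_gives_empty_mask(self, rng):
        filt = rng.random((4, 8, 8))
        params = DetectionParams(threshold="absolute:5")
        assert not make_mask(filt, params).any()

    def test_quantile_zero_keeps_everything_above_the_minimum(self, rng):
        filt = rng.random((4, 8, 8))
        params = DetectionParams(threshold="quantile:0")
        mask = make_mask(filt, params)
        np.testing.assert_array_equal(mask, filt > filt.min())

    def test_otsu_recovers_exact_support_of_two_level_image(self):
        filt = np.zeros((6, 16, 16))
        filt[2:4, 4:9, 5:10] = 10.0
        mask = make_mask(filt, DetectionParams())  # default otsu
        np.testing.assert_array_equal(mask, filt > 5.0)  # any cut in (0,10) works

    def test_otsu_on_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="absolute"):
            make_mask(np.ones((2, 4, 4)), DetectionParams())


class TestExtractNuclei:
    def test_empty_mask_yields_empty_list(self):
        assert extract_nuclei(np.zeros((4, 8, 8), bool), UNIT) == []

    def test_components_below_min_volume_discarded(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2, 2, 2:7] = True  # 5 voxels = 5 µm³ at unit spacing
        params = DetectionParams(min_volume_um3=6.0, split_touching=False)
        assert extract_nuclei(mask, UNIT, params) == []

    def test_digital_ball_radius_matches_closed_form(self):
        zz, yy, xx = np.mgrid[:24, :24, :24]
        ball = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 10.0 ** 2
        params = DetectionParams(max_volume_um3=1e5, split_touching=False)
        (det,) = extract_nuclei(ball, UNIT, params)
        assert det.voxel_count == int(ball.sum())
        expected_r = (3 * det.voxel_count / (4 * np.pi)) ** (1 / 3)
        assert det.equivalent_radius_um == pytest.approx(expected_r)
        assert det.equivalent_radius_um == pytest.approx(10.0, rel=0.02)
        np.testing.assert_allclose(det.centroid_um, (12, 12, 12), atol=1e-9)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity, rng):
        """Connected components agree with brute-force BFS on random grids."""
        params = DetectionParams(connectivity=connectivity, split_touching=False,
                                 min_volume_um3=0.0, max_volume_um3=1e9)
        for _ in range(10):
            mask = rng.random((16, 16, 16)) < 0.25
            structure = ndi.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
            labels, _ = ndi.label(mask, structure=structure)
            assert labels_to_partition(labels) == flood_fill_components(mask, connectivity)
            # and the measured detections cover every component exactly once
            dets = extract_nuclei(mask, UNIT, params)
            assert len(dets) == labels.max()

    def test_mean_radius_is_arithmetic_mean(self):
        dets = [NucleusDetection(1, (0, 0, 0), 10, 2.0),
                NucleusDetection(2, (1, 1, 1), 10, 4.0)]
        assert estimate_mean_radius(dets) == pytest.approx(3.0)

    def test_mean_radius_of_nothing_is_an_error(self):
        with pytest.raises(ValidationError):
            estimate_mean_radius([])


def _blob_volume(centers, shape=(48, 48, 48), sigma=2.0, amp=50.0):
    vol = np.zeros(shape)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    for cz, cy, cx in centers:
        vol += amp * np.exp(-((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
                            / (2 * sigma ** 2))
    return vol


class TestDetectionProperties:
    PARAMS = DetectionParams(sigma_small_um=1.0, sigma_wide_um=3.0,
                             threshold="absolute:4.0", min_volume_um3=8.0)

    def test_integer_shift_translates_all_centroids(self):
        """Translating the volume by whole voxels translates every centroid
        by the same physical offset (interior nuclei, fixed threshold)."""
        centers = [(20, 18, 22), (24, 30, 16), (30, 22, 30)]
        shift = (2, 5, 3)
        a = detect_nuclei(_blob_volume(centers), UNIT, self.PARAMS)
        b = detect_nuclei(_blob_volume([tuple(c + s for c, s in zip(cc, shift))
                                        for cc in centers]), UNIT, self.PARAMS)
        assert len(a) == len(b) == 3
        for da, db in zip(a, b):
            np.testing.assert_allclose(
                np.asarray(db.centroid_um) - np.asarray(da.centroid_um),
                shift, atol=1e-6)

    @pytest.mark.parametrize("rule", ["otsu", "quantile:0.97"])
    def test_intensity_scale_invariance(self, small_volume_clean, rule):
        params = DetectionParams(threshold=rule)
        grid = small_volume_clean.channel("dapi")
        a = detect_nuclei(grid, small_volume_clean.spacing, params)
        b = detect_nuclei(3.7 * grid, small_volume_clean.spacing, params)
        assert [d.centroid_um for d in a] == [d.centroid_um for d in b]
        assert [d.voxel_count for d in a] == [d.voxel_count for d in b]

    def test_noise_free_scene_counted_exactly(self):
        df = count_recovery([50], [7])
        row = df.iloc[0]
        assert row.n_detected == row.n_true == 50
        assert row.max_centroid_error_vox <= 1.0

    def test_noisy_scene_recall_and_precision(self):
        df = count_recovery([80], [21], noise=NoiseModel())
        row = df.iloc[0]
        assert row.recall >= 0.95 and row.precision >= 0.95

    def test_radius_recovered_within_15_percent(self):
        scene = sample_scene(count_scene_params(60), 13)
        vol = render_scene(scene, NoiseModel())
        dets = detect_nuclei(vol.channel("dapi"), scene.spacing)
        est = estimate_mean_radius(dets)
        assert est == pytest.approx(scene.mean_radius_um(), rel=0.15)


class TestThresholdRule:
    def test_parse_round_trip(self):
        assert str(ThresholdRule.parse("quantile:0.9")) == "quantile:0.9"
        assert ThresholdRule.parse("otsu").kind == "otsu"

    def test_unknown_rule_names_the_allowed_ones(self):
        with pytest.raises(ValidationError, match="otsu, quantile, absolute"):
            ThresholdRule.parse("mean+2sd")
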