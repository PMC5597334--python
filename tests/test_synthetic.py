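import dataclasses

import numpy as np
import pytest

from lgquant import (NOISELESS, GroundTruthScene, NoiseModel, Nucleus,
                     PackingError, SceneParams, pearson_colocalization,
                     render_barrier_pair, render_scene, sample_scene)


def _params(**kw):
    base = dict(shape=(16, 64, 64), spacing=(1.0, 0.3, 0.3), n_nuclei=10,
                psc_count=0, marker_fractions={"plasmatocyte": 0.3})
    base.update(kw)
    return SceneParams(**base)


class TestSampling:
    def test_marker_counts_are_exact(self):
        scene = sample_scene(_params(shape=(24, 96, 96), n_nuclei=30), seed=1)
        assert scene.marker_count("plasmatocyte") == 9
        assert scene.true_index("plasmatocyte") == pytest.approx(0.3)

    def test_identical_params_and_seed_give_identical_scenes(self):
        a = sample_scene(_params(), seed=5)
        b = sample_scene(_params(), seed=5)
        assert a == b
        c = sample_scene(_params(), seed=6)
        assert a != c

    def test_min_separation_respected(self):
        scene = sample_scene(_params(shape=(24, 96, 96), n_nuclei=15), seed=2)
        pts = np.array([n.center_um for n in scene.nuclei])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= scene.params.min_separation

    def test_infeasible_packing_raises(self):
        # 50 nuclei at 10 µm separation cannot fit a 20x20x20 µm box
        params = _params(shape=(20, 67, 67), n_nuclei=50, min_separation=10.0)
        with pytest.raises(PackingError, match="cannot pack"):
            sample_scene(params, seed=1)

    def test_psc_nuclei_lie_inside_exclusion_region(self):
        params = _params(shape=(24, 96, 96), n_nuclei=12, psc_count=4,
                         min_separation=4.0, psc_center_frac=(0.5, 0.5, 0.6),
                         psc_semiaxes=(6.0, 6.0, 6.0))
        scene = sample_scene(params, seed=3)
        mask = scene.exclusion_mask()
        for nuc in scene.nuclei:
            idx = tuple(int(round(c / s)) for c, s in zip(nuc.center_um, scene.spacing))
            assert mask.voxels[idx] == (nuc.region == "PSC")


class TestRendering:
    def test_zero_nuclei_scene_is_exactly_the_background(self):
        scene = sample_scene(_params(n_nuclei=0, marker_fractions={}), seed=1)
        vol = render_scene(scene, NOISELESS)
        g = vol.channel("dapi")
        p = scene.params
        expected = p.background_base + p.background_gradient * (
            np.arange(p.shape[2]) / (p.shape[2] - 1))
        np.testing.assert_allclose(g, np.broadcast_to(expected, p.shape))

    def test_peak_value_at_a_nucleus_centred_on_a_voxel(self):
        """Noise-free limit: at an on-grid nucleus centre the nuclear channel
        equals background plus the blob amplitude."""
        p = _params(n_nuclei=0, marker_fractions={}, background_gradient=0.0)
        nuc = Nucleus(id=0, center_um=(8.0, 9.6, 9.6), radius_um=2.4, region="MZ")
        scene = GroundTruthScene(params=p, nuclei=(nuc,), seed=0)
        g = render_scene(scene, NOISELESS).channel("dapi")
        assert g[8, 32, 32] == pytest.approx(p.background_base + p.nuclear_amplitude)
        assert g.argmax() == np.ravel_multi_index((8, 32, 32), p.shape)

    def test_render_invariant_under_nucleus_relabeling(self):
        scene = sample_scene(_params(), seed=9)
        flipped = dataclasses.replace(scene, nuclei=tuple(reversed(scene.nuclei)))
        a = render_scene(scene, NOISELESS)
        b = render_scene(flipped, NOISELESS)
        for name in a.channel_names:
            np.testing.assert_array_equal(a.channel(name), b.channel(name))

    def test_render_deterministic_for_fixed_seed(self):
        scene = sample_scene(_params(), seed=4)
        noise = NoiseModel()
        a = render_scene(scene, noise, seed=123)
        b = render_scene(scene, noise, seed=123)
        for name in a.channel_names:
            np.testing.assert_array_equal(a.channel(name), b.channel(name))

    def test_noise_model_is_unbiased_at_a_fixed_voxel(self):
        """Monte-Carlo: the mean of repeated noisy renders converges on the
        noiseless value (within 3 standard errors)."""
        p = _params(shape=(8, 24, 24), n_nuclei=0, marker_fractions={},
                    background_gradient=0.0)
        nuc = Nucleus(id=0, center_um=(4.0, 3.6, 3.6), radius_um=2.0, region="MZ")
        scene = GroundTruthScene(params=p, nuclei=(nuc,), seed=0)
        clean = render_scene(scene, NOISELESS).channel("dapi")[4, 12, 12]
        noise = NoiseModel(photon_scale=2.0, read_sigma=2.0)
        draws = np.array([
            render_scene(scene, noise, seed=s).channel("dapi")[4, 12, 12]
            for s in range(200)])
        sem = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - clean) < 3 * sem + 1e-9


class TestBarrierPair:
    def _scene(self, seed=2):
        params = _params(shape=(24, 96, 96), n_nuclei=24, psc_count=5,
                         min_separation=5.0, marker_fractions={},
                         psc_center_frac=(0.5, 0.5, 0.7),
                         psc_semiaxes=(7.0, 7.0, 7.0))
        return sample_scene(params, seed)

    def test_intact_barrier_excludes_large_dye_from_niche(self):
        scene = self._scene()
        vol = render_barrier_pair(scene, NOISELESS, barrier_intact=True)
        excl = scene.exclusion_mask().voxels
        large = vol.channel("dye70")
        small = vol.channel("dye40")
        # complete exclusion: only background remains inside the region
        np.testing.assert_allclose(large[excl], scene.params.dye_background)
        assert small[excl].max() > scene.params.dye_background + 1

    def test_broken_barrier_renders_dyes_identically(self):
        scene = self._scene()
        vol = render_barrier_pair(scene, NOISELESS, barrier_intact=False)
        np.testing.assert_array_equal(vol.channel("dye70"), vol.channel("dye40"))

    def test_pearson_in_niche_separates_intact_from_broken(self):
        scene = self._scene()
        noise = NoiseModel()
        roi = scene.exclusion_mask()
        r = {}
        for intact in (True, False):
            vol = render_barrier_pair(scene, noise, barrier_intact=intact)
            r[intact] = pearson_colocalization(vol, "dye40", "dye70", roi).pearson_r
        assert r[False] > r[True] + 0.5
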