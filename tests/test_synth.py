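"""Synthetic lambda-stack generator: panel shapes, scene contracts, rendering."""

import numpy as np
import pytest

import specunmix as su
from specunmix.synth import (
    DEFAULT_GRID,
    GroundTruthScene,
    NoiseModel,
    SceneSpec,
    SynthError,
    make_panel,
    make_scene,
    render,
)


class TestPanel:
    def test_default_peaks_land_on_nearest_bands(self, panel):
        expected = {"DAPI": 461, "Opal520": 520, "Opal570": 570,
                    "Opal620": 620, "Opal690": 690}
        for label, peak in expected.items():
            band = panel.wavelengths[np.argmax(panel.spectra[label])]
            nearest = panel.wavelengths[np.argmin(np.abs(panel.wavelengths - peak))]
            assert band == nearest, label

    def test_every_spectrum_is_unit_max(self, panel):
        for label, s in panel.spectra.items():
            assert s.max() == pytest.approx(1.0), label
            assert s.min() >= 0.0

    def test_neighboring_dyes_overlap_more_than_distant_ones(self, panel):
        def corr(a, b):
            return np.corrcoef(panel.spectra[a], panel.spectra[b])[0, 1]

        assert corr("Opal570", "Opal620") > corr("Opal520", "Opal690")

    def test_dapi_has_secondary_lobe_toward_green(self, panel):
        s = panel.spectra["DAPI"]
        grid = panel.wavelengths
        # non-trivial energy remains at 510-530 nm, the bleed into the 520 dye
        assert s[(grid >= 505) & (grid <= 530)].max() > 0.25

    def test_peak_far_outside_grid_rejected(self):
        with pytest.raises(SynthError, match="outside"):
            make_panel(peaks={"X": 800.0})

    def test_lipofuscin_is_broad(self, panel):
        lipo = panel.spectra["lipofuscin"]
        dye = panel.spectra["Opal570"]
        assert np.mean(lipo) > 2 * np.mean(dye)


class TestScene:
    def test_deterministic_per_seed(self):
        s1 = make_scene((2, 32, 32), seed=9)
        s2 = make_scene((2, 32, 32), seed=9)
        for l in s1.labels:
            assert np.array_equal(s1.abundances[l], s2.abundances[l])
        assert np.array_equal(s1.background, s2.background)

    def test_zero_densities_give_background_one(self):
        spec = SceneSpec(puncta_per_1000px3=0.0, lipofuscin_per_1000px3=0.0, n_nuclei=0)
        s = make_scene((1, 16, 16), spec=spec, seed=0)
        for l in s.labels:
            assert np.all(s.abundances[l] == 0)
        assert np.all(s.background == 1.0)

    def test_abundances_plus_background_complete_to_one(self):
        s = make_scene((2, 48, 48), seed=1)
        total = sum(s.abundances.values())
        assert total.max() <= 1.0 + 1e-12
        assert np.array_equal(s.background, np.maximum(1.0 - total, 0.0))

    def test_puncta_counts_follow_poisson_contract(self):
        lam = 3.0
        shape = (2, 24, 24)
        V = np.prod(shape)
        counts = [
            len(make_scene(shape, gene_labels=["g"], seed=s, include_dapi=False,
                           include_lipofuscin=False,
                           spec=SceneSpec(puncta_per_1000px3=lam)).objects["puncta"]["g"])
            for s in range(50)
        ]
        expected = lam * V / 1000.0
        tol = 3 * np.sqrt(expected / 50)
        assert abs(np.mean(counts) - expected) < tol

    def test_too_small_shape_rejected(self):
        with pytest.raises(SynthError, match="too small"):
            make_scene((1, 4, 4), seed=0)


class TestRender:
    def test_noise_free_satisfies_linear_model_to_quantization(self, panel):
        scene = make_scene((2, 32, 32), seed=2)
        stack, truth = render(panel, scene, seed=3)
        F = su.normalize_stack(stack).F
        model = truth.endmembers.S @ truth.A
        assert np.abs(F - model).max() <= 0.5 / stack.dtype_max + 1e-12

    def test_single_pure_pixel_renders_exactly(self, panel):
        maps = {"Opal570": np.zeros((1, 1, 1))}
        maps["Opal570"][0, 0, 0] = 1.0
        scene = GroundTruthScene(shape=(1, 1, 1), abundances=maps,
                                 background=np.zeros((1, 1, 1)))
        stack, truth = render(panel, scene, seed=0)
        got = stack.data[0, 0, 0] / stack.dtype_max
        assert np.abs(got - panel.spectra["Opal570"]).max() <= 0.5 / stack.dtype_max

    def test_disjoint_scenes_add_linearly(self, panel):
        shape = (1, 8, 8)
        a = np.zeros(shape)
        b = np.zeros(shape)
        a[0, :4, :] = 0.6
        b[0, 4:, :] = 0.8
        sc_a = GroundTruthScene(shape, {"Opal520": a.copy()}, 1.0 - a)
        sc_b = GroundTruthScene(shape, {"Opal520": b.copy()}, 1.0 - b)
        sc_ab = GroundTruthScene(shape, {"Opal520": a + b}, 1.0 - a - b)
        empty = GroundTruthScene(shape, {"Opal520": np.zeros(shape)}, np.ones(shape))
        Fs = [render(panel, s, seed=0)[1].F_clean for s in (sc_a, sc_b, sc_ab, empty)]
        np.testing.assert_allclose(Fs[0] + Fs[1] - Fs[3], Fs[2], atol=1e-12)

    def test_requested_snr_is_achieved_empirically(self, panel):
        """Mean realized SNR over 50 noise draws is within 1 dB of the target."""
        scene = make_scene((1, 24, 24), seed=4)
        target = 30.0
        _, clean = render(panel, scene, seed=0)
        signal = clean.A[:-1].sum(axis=0) > 0
        p_sig = np.mean(clean.F_clean[:, signal] ** 2)
        snrs = []
        for s in range(50):
            stack, truth = render(panel, scene, noise=NoiseModel(target_snr_db=target),
                                  seed=s)
            F = su.normalize_stack(stack).F
            noise_p = np.mean((F[:, signal] - truth.F_clean[:, signal]) ** 2)
            snrs.append(10 * np.log10(p_sig / noise_p))
        assert abs(np.mean(snrs) - target) < 1.0

    def test_stacks_reproducible_bit_exactly(self, panel):
        scene = make_scene((1, 16, 16), seed=5)
        s1, _ = render(panel, scene, noise=NoiseModel(target_snr_db=25), seed=6)
        s2, _ = render(panel, scene, noise=NoiseModel(target_snr_db=25), seed=6)
        assert np.array_equal(s1.data, s2.data)

    def test_quantization_floor_warns(self, panel):
        scene = make_scene((1, 16, 16), seed=7)
        scene_dim = GroundTruthScene(
            scene.shape,
            {l: m * 1e-6 for l, m in scene.abundances.items()},
            np.zeros(scene.shape),  # no background light: only the dim dyes remain
        )
        with pytest.warns(UserWarning, match="quantizes"):
            render(panel, scene_dim, dtype=np.uint8, seed=0)


class TestPureMosaic:
    def test_partition_is_exact_and_covers_all_labels(self):
        labels = ["a", "b", "c"]
        panel_labels = labels + ["background"]
        scene = su.make_pure_mosaic_scene((1, 16, 16), labels, seed=0)
        total = sum(scene.abundances.values()) + scene.background
        assert np.all(total == 1.0)
        for l in labels:
            assert scene.abundances[l].sum() > 0
        stacked = np.stack([scene.abundances[l] for l in labels] + [scene.background])
        assert np.all(stacked.max(axis=0) == 1.0)  # every pixel pure
        assert len(panel_labels) == 4
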