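"""The synthetic scene/trial generator: exact cover bookkeeping, endmember
spectra, treatment structure and reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from canopyvi import (SceneParams, TrialDesign, generate_canopy_scene,
                      generate_trial, green_area, greener_area,
                      leaf_soil_reflectance, spectral_index,
                      summarize_spectral_plot)
from canopyvi.synthetic import (LEAF_SPECTRUM_HEALTHY, SOIL_SPECTRUM)


class TestEndmemberSpectra:
    def test_healthy_leaf_has_red_absorption_and_nir_plateau(self):
        assert leaf_soil_reflectance(840, "leaf") > leaf_soil_reflectance(670, "leaf")
        assert LEAF_SPECTRUM_HEALTHY[670] < 0.1

    def test_soil_ndvi_is_low(self):
        ndvi = spectral_index("ndvi", {670: SOIL_SPECTRUM[670], 840: SOIL_SPECTRUM[840]})
        assert ndvi < 0.2

    def test_chlorosis_moves_bands_monotonically(self):
        reds = [leaf_soil_reflectance(670, "leaf", c) for c in (0.0, 0.3, 0.7, 1.0)]
        nirs = [leaf_soil_reflectance(840, "leaf", c) for c in (0.0, 0.3, 0.7, 1.0)]
        assert reds == sorted(reds) and reds[0] < reds[-1]
        assert nirs == sorted(nirs, reverse=True) and nirs[0] > nirs[-1]

    def test_chlorotic_leaf_ndvi_lower(self):
        healthy = spectral_index("ndvi", {670: leaf_soil_reflectance(670, "leaf", 0.0),
                                          840: leaf_soil_reflectance(840, "leaf", 0.0)})
        sick = spectral_index("ndvi", {670: leaf_soil_reflectance(670, "leaf", 1.0),
                                       840: leaf_soil_reflectance(840, "leaf", 1.0)})
        assert sick < healthy

    def test_unsupported_wavelength_rejected(self):
        with pytest.raises(ValueError):
            leaf_soil_reflectance(640, "leaf")
        with pytest.raises(ValueError):
            leaf_soil_reflectance(670, "bark")


class TestSceneGeneration:
    def test_pure_soil_scene_has_zero_green_area(self):
        img, _, truth = generate_canopy_scene(
            SceneParams(green_fraction=0.0, image_size=(64, 48), seed=5))
        assert truth.n_green == 0
        assert green_area(img) == 0.0

    def test_cover_target_realized_within_tolerance(self):
        img, _, truth = generate_canopy_scene(
            SceneParams(green_fraction=0.25, image_size=(192, 128), seed=9))
        assert truth.true_green_fraction == pytest.approx(0.25, abs=1e-4)
        assert green_area(img) == pytest.approx(0.25, abs=0.01)

    def test_computed_ga_matches_pixel_bookkeeping(self, small_scene):
        img, _, truth = small_scene
        assert green_area(img) == pytest.approx(truth.true_green_fraction, abs=0.005)
        assert greener_area(img) == pytest.approx(truth.true_gga_fraction, abs=0.005)

    def test_rgb_and_stack_are_pixel_aligned(self, small_scene):
        img, stack, _ = small_scene
        assert stack.shape == img.pixels.shape[:2]

    def test_determinism_from_seed(self):
        p = SceneParams(green_fraction=0.2, chlorosis=0.4, purpling=0.3,
                        image_size=(96, 64), seed=21)
        a_img, a_stack, a_truth = generate_canopy_scene(p)
        b_img, b_stack, b_truth = generate_canopy_scene(p)
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert all(np.array_equal(a_stack.bands[wl], b_stack.bands[wl])
                   for wl in a_stack.bands)
        assert a_truth == b_truth

    def test_chlorosis_lowers_scene_ndvi_at_equal_cover(self):
        kw = dict(green_fraction=0.3, image_size=(128, 96))
        healthy = generate_canopy_scene(SceneParams(chlorosis=0.0, seed=3, **kw))[1]
        sick = generate_canopy_scene(SceneParams(chlorosis=1.0, seed=3, **kw))[1]
        assert summarize_spectral_plot(sick).ndvi < summarize_spectral_plot(healthy).ndvi

    def test_chlorosis_shrinks_greener_area(self):
        kw = dict(green_fraction=0.3, image_size=(128, 96), seed=7)
        mild = generate_canopy_scene(SceneParams(chlorosis=0.1, **kw))
        strong = generate_canopy_scene(SceneParams(chlorosis=0.9, **kw))
        assert strong[2].n_gga < mild[2].n_gga
        assert greener_area(strong[0]) < greener_area(mild[0])

    def test_cover_ranking_matches_ndvi_ranking(self):
        # constant chlorosis: more canopy -> more NIR contrast, same order
        fractions = [0.05, 0.15, 0.25, 0.35]
        ndvis, truths = [], []
        for i, gf in enumerate(fractions):
            _, stack, truth = generate_canopy_scene(
                SceneParams(green_fraction=gf, image_size=(96, 64), seed=31 + i))
            ndvis.append(summarize_spectral_plot(stack).ndvi)
            truths.append(truth.true_green_fraction)
        assert np.argsort(ndvis).tolist() == np.argsort(truths).tolist()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(green_fraction=1.5)
        with pytest.raises(ValueError):
            SceneParams(image_size=(4, 4))


class TestTrialGeneration:
    def small_design(self, **kw):
        defaults = dict(image_size=(48, 32), seed=100)
        defaults.update(kw)
        return TrialDesign(**defaults)

    def test_default_design_yields_52_plots(self):
        plots = generate_trial(self.small_design())
        assert len(plots) == 52
        treatments = {p.record.treatment for p in plots}
        assert treatments == {"NPF", "OP"}
        assert len({p.record.plot_id for p in plots}) == 52

    def test_same_seed_reproduces_everything(self):
        a = generate_trial(self.small_design(n_genotypes=4))
        b = generate_trial(self.small_design(n_genotypes=4))
        for pa, pb in zip(a, b):
            assert pa.record.grain_yield == pb.record.grain_yield
            assert pa.record.leaf_p == pb.record.leaf_p
            assert np.array_equal(pa.rgb.pixels, pb.rgb.pixels)

    def test_degenerate_design_has_zero_yield_variance(self):
        design = self.small_design(cover_yield_slope=0.0, genotype_sd=0.0,
                                   residual_sd=0.0, n_genotypes=4)
        plots = generate_trial(design)
        for t in ("NPF", "OP"):
            ys = [p.record.grain_yield for p in plots if p.record.treatment == t]
            assert np.var(ys) == 0.0
            assert ys[0] == pytest.approx(design.mean_yield[t])

    def test_treatment_means_recovered_at_scale(self):
        # many plots per arm: sample means should sit within 3 SE of the
        # configured 5.64 / 7.50 t/ha
        design = self.small_design(n_genotypes=150, seed=42)
        plots = generate_trial(design)
        per_plot_sd = np.sqrt((design.cover_yield_slope * design.cover_sd["NPF"]) ** 2
                              + design.genotype_sd ** 2 + design.residual_sd ** 2)
        for t in ("NPF", "OP"):
            ys = np.array([p.record.grain_yield for p in plots if p.record.treatment == t])
            se = per_plot_sd / np.sqrt(len(ys))
            assert abs(ys.mean() - design.mean_yield[t]) < 3 * se

    def test_npf_arm_is_less_covered_and_more_chlorotic(self):
        plots = generate_trial(self.small_design(n_genotypes=30, seed=8))
        cover = {t: np.mean([p.truth.true_green_fraction for p in plots
                             if p.record.treatment == t]) for t in ("NPF", "OP")}
        chl = {t: np.mean([p.record.extra["chlorosis"] for p in plots
                           if p.record.treatment == t]) for t in ("NPF", "OP")}
        assert cover["NPF"] < cover["OP"]
        assert chl["NPF"] > chl["OP"]

    def test_planted_cover_yield_correlation_recovered(self):
        # across seeds, the mean within-treatment correlation between
        # computed GA and yield should track the closed-form planted value
        design = self.small_design()
        rs = {"NPF": [], "OP": []}
        for seed in range(12):
            plots = generate_trial(dataclasses.replace(design, seed=200 + seed))
            for t in ("NPF", "OP"):
                ga = [green_area(p.rgb) for p in plots if p.record.treatment == t]
                gy = [p.record.grain_yield for p in plots if p.record.treatment == t]
                rs[t].append(sps.pearsonr(ga, gy)[0])
        for t in ("NPF", "OP"):
            planted = design.planted_cover_yield_correlation(t)
            assert np.mean(rs[t]) == pytest.approx(planted, abs=0.15)

    def test_traits_follow_treatment_models(self):
        # pool three seeds (600 plots) so the 3-SE band has real power
        vals = {"NPF": [], "OP": []}
        for seed in (77, 78, 79):
            plots = generate_trial(self.small_design(n_genotypes=100, seed=seed))
            for p in plots:
                vals[p.record.treatment].append(p.record.leaf_p)
        for t, mean_p in (("NPF", 2.06), ("OP", 4.81)):
            v = np.array(vals[t])
            assert v.mean() == pytest.approx(mean_p, abs=3 * v.std(ddof=1) / np.sqrt(len(v)))

    def test_design_validation(self):
        with pytest.raises(ValueError):
            TrialDesign(n_genotypes=1)
        with pytest.raises(ValueError):
            TrialDesign(genotype_sd=-1)
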