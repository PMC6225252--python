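import dataclasses

import numpy as np
import pandas as pd
import pytest

from chrysaspec.hypercube import calibrate_reflectance, nearest_band
from chrysaspec.synthetic import (
    FLAV_TROUGH_COEF,
    FLAV_TROUGH_NM,
    FLAV_TROUGH_SIGMA_NM,
    POLY_TROUGH_COEF,
    POLY_TROUGH_NM,
    POLY_TROUGH_SIGMA_NM,
    REFLECTANCE_PEAKS,
    FlowerClassSpec,
    PlacementError,
    SceneConfig,
    default_classes,
    simulate_dataset,
)

from conftest import make_scene


def closed_form_signature(poly, flav, cls, wavelengths):
    """Independently coded closed-form evaluation of the signature."""
    r = np.full_like(wavelengths, cls.baseline_reflectance, dtype=float)
    for c, a, s in REFLECTANCE_PEAKS:
        r += a * np.exp(-((wavelengths - c) ** 2) / (2 * s * s))
    r -= POLY_TROUGH_COEF * poly * np.exp(
        -((wavelengths - POLY_TROUGH_NM) ** 2) / (2 * POLY_TROUGH_SIGMA_NM ** 2))
    r -= FLAV_TROUGH_COEF * flav * np.exp(
        -((wavelengths - FLAV_TROUGH_NM) ** 2) / (2 * FLAV_TROUGH_SIGMA_NM ** 2))
    return r


class TestSignatureSpectrum:
    def test_zero_content_is_baseline_plus_peaks(self, axis):
        from chrysaspec.synthetic import signature_spectrum
        cls = default_classes()[0]
        spec = signature_spectrum(0.0, 0.0, cls, axis)
        oracle = closed_form_signature(0.0, 0.0, cls, axis.wavelengths_nm)
        np.testing.assert_allclose(spec, oracle, atol=1e-14)
        # no troughs: spectrum never dips below the baseline
        assert spec.min() >= cls.baseline_reflectance - 1e-12

    def test_matches_independent_closed_form(self, axis):
        from chrysaspec.synthetic import signature_spectrum
        cls = default_classes()[1]
        spec = signature_spectrum(3.76, 9.11, cls, axis)
        oracle = closed_form_signature(3.76, 9.11, cls, axis.wavelengths_nm)
        np.testing.assert_allclose(spec, oracle, atol=1e-14)

    def test_monotone_in_content_at_trough_center(self, axis):
        from chrysaspec.synthetic import signature_spectrum
        cls = default_classes()[1]
        band = nearest_band(axis, POLY_TROUGH_NM)
        vals = [signature_spectrum(p, 9.11, cls, axis)[band]
                for p in np.linspace(3.4, 4.3, 7)]
        assert np.all(np.diff(vals) < 0)

    def test_out_of_range_contents_rejected(self, axis):
        from chrysaspec.synthetic import signature_spectrum
        cls = default_classes()[0]
        with pytest.raises(ValueError):
            signature_spectrum(50.0, 0.0, cls, axis)  # trough below 0
        with pytest.raises(ValueError):
            signature_spectrum(-1.0, 9.0, cls, axis)


class TestRenderScene:
    def test_zero_noise_round_trip_is_exact(self, tiny_config):
        scene = make_scene(tiny_config, noise_sd=0.0)
        cube = calibrate_reflectance(scene.raw, scene.dark, scene.white,
                                     axis=scene.axis)
        # every flower pixel carries exactly its signature spectrum
        from chrysaspec.synthetic import signature_spectrum
        cls = default_classes()[1]
        expected = signature_spectrum(3.76, 9.11, cls, scene.axis)
        fg = scene.label_mask > 0
        err = np.abs(cube.data[fg] - expected).max()
        assert err < 1e-10
        bg_err = np.abs(cube.data[~fg] - 0.05).max()
        assert bg_err < 1e-10

    def test_dark_strictly_below_white(self, tiny_config):
        scene = make_scene(tiny_config)
        assert (scene.white > scene.dark).all()

    def test_fixed_seed_reproducible(self, tiny_config):
        a = make_scene(tiny_config, seed=5)
        b = make_scene(tiny_config, seed=5)
        np.testing.assert_array_equal(a.raw, b.raw)
        np.testing.assert_array_equal(a.label_mask, b.label_mask)

    def test_mask_matches_disk_footprints(self, tiny_config):
        scene = make_scene(tiny_config, noise_sd=0.0)
        cls = default_classes()[1]
        for _, fl in scene.flowers.iterrows():
            m = scene.label_mask == fl.flower_id
            yy, xx = np.nonzero(m)
            inside = ((yy - fl.center_y) ** 2 + (xx - fl.center_x) ** 2
                      <= cls.radius_px ** 2)
            assert inside.all()
            assert m.sum() == fl.area_px

    def test_impossible_placement_raises(self):
        cfg = SceneConfig(image_width_px=50, image_length_px=50,
                          n_flowers_per_sample=12, n_samples_per_class=1)
        with pytest.raises(PlacementError):
            make_scene(cfg, class_spec=default_classes()[2])


class TestSimulateDataset:
    def test_study_scale_yields_279_samples(self):
        cfg = SceneConfig(n_samples_per_class=93)
        sim = simulate_dataset(cfg)
        assert sim.n_samples == 279
        assert len(sim.ground_truth.samples) == 279

    def test_every_flower_belongs_to_one_sample(self, small_dataset):
        flowers = small_dataset.ground_truth.flowers
        counts = flowers.groupby(["sample_id", "flower_id"]).size()
        assert (counts == 1).all()
        n = small_dataset.config.n_flowers_per_sample
        assert (flowers.groupby("sample_id").size() == n).all()

    def test_contents_within_class_range(self, small_dataset):
        truth = small_dataset.ground_truth.samples
        for cls in small_dataset.classes:
            sub = truth[truth.class_name == cls.name]
            lo, hi = cls.content_range("polysaccharides")
            assert sub.poly_pct.between(lo, hi).all()
            lo, hi = cls.content_range("flavonoids")
            assert sub.flav_pct.between(lo, hi).all()

    def test_class_statistics_converge(self):
        # chemistry only (no scene rendering) at n=500 per class
        cfg = SceneConfig(n_samples_per_class=500, seed=123)
        sim = simulate_dataset(cfg)
        truth = sim.ground_truth.samples
        n = 500
        for cls in sim.classes:
            sub = truth[truth.class_name == cls.name]
            se_mean = cls.poly_sd / np.sqrt(n)
            assert abs(sub.poly_pct.mean() - cls.poly_mean) < 3 * se_mean
            se_mean = cls.flav_sd / np.sqrt(n)
            assert abs(sub.flav_pct.mean() - cls.flav_mean) < 3 * se_mean
            # SDs within 3 standard errors (SE(sd) ~ sd/sqrt(2n))
            assert abs(sub.poly_pct.std(ddof=1) - cls.poly_sd) \
                < 3 * cls.poly_sd / np.sqrt(2 * n)
            assert abs(sub.flav_pct.std(ddof=1) - cls.flav_sd) \
                < 3 * cls.flav_sd / np.sqrt(2 * n)

    def test_pooled_sds_match_reference_summary(self):
        cfg = SceneConfig(n_samples_per_class=500, seed=42)
        truth = simulate_dataset(cfg).ground_truth.samples
        assert abs(truth.poly_pct.std(ddof=1) - 0.28) < 0.03
        assert abs(truth.flav_pct.std(ddof=1) - 0.86) < 0.07

    def test_scene_regeneration_is_deterministic(self, small_dataset):
        a = small_dataset.scene(4)
        b = small_dataset.scene(4)
        np.testing.assert_array_equal(a.raw, b.raw)

    def test_content_reflectance_identifiability(self, small_dataset):
        """Polysaccharide content must drive the 1210 nm trough: strong
        negative correlation across samples at default noise."""
        sim = small_dataset
        band = nearest_band(sim.config.axis(), POLY_TROUGH_NM)
        vals, polys = [], []
        for scene in sim.iter_scenes():
            cube = calibrate_reflectance(scene.raw, scene.dark, scene.white,
                                         axis=scene.axis)
            fg = scene.label_mask > 0
            vals.append(cube.data[fg, band].mean())
            polys.append(sim.ground_truth.samples.loc[
                sim.ground_truth.samples.sample_id == scene.sample_id,
                "poly_pct"].iloc[0])
        r = np.corrcoef(polys, vals)[0, 1]
        assert r < -0.8

    def test_class_ordering_enforced(self):
        bad = (
            FlowerClassSpec("small", 8, 0.40, 4.0, 0.1, 10.0, 0.4),
            FlowerClassSpec("medium", 14, 0.42, 3.5, 0.1, 9.0, 0.4),
            FlowerClassSpec("big", 20, 0.44, 4.5, 0.1, 8.0, 0.4),
        )
        with pytest.raises(ValueError):
            simulate_dataset(SceneConfig(n_samples_per_class=2), classes=bad)
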