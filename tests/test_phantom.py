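"""Phantom generator: chromophore panel shapes, rendering physics,
determinism, and the class-separability contracts."""

import numpy as np
import pytest

from mslesion import phantom
from mslesion.phantom import (CLASS_NAMES, ChromophorePanel, PhantomError,
                              SimulationConfig, SpectralBandSet,
                              build_default_chromophore_panel,
                              expected_lesion_reflectance, read_capture,
                              render_capture, simulate_dataset,
                              synthesize_lesion, write_capture)


class TestChromophorePanel:
    def test_default_panel_has_required_spectral_shapes(self):
        panel = build_default_chromophore_panel()
        assert panel.coefficient("melanin", 414) > panel.coefficient("melanin", 995)
        assert panel.coefficient("water", 995) > panel.coefficient("water", 414)
        # hemoglobin minimum near the red band
        oxy = panel.absorption["oxyhemoglobin"]
        assert min(oxy) == panel.coefficient("oxyhemoglobin", 671)

    def test_single_band_panel_is_degenerate_but_valid(self):
        panel = build_default_chromophore_panel(SpectralBandSet((671.0,)))
        for name in phantom.CHROMOPHORES:
            assert len(panel.absorption[name]) == 1

    def test_band_set_must_increase(self):
        with pytest.raises(PhantomError):
            SpectralBandSet((500.0, 450.0))

    def test_melanin_must_be_monotone(self):
        bands = SpectralBandSet((400.0, 500.0))
        with pytest.raises(PhantomError):
            ChromophorePanel(bands=bands, absorption={"melanin": (0.1, 0.9)})


class TestSynthesizeLesion:
    def test_concentrations_fall_in_class_ranges(self):
        config = SimulationConfig(frame_shape=(32, 32))
        rng = np.random.default_rng(0)
        for label in CLASS_NAMES:
            lesion = synthesize_lesion(config, label, rng)
            for chromo, (lo, hi) in config.class_concentration_ranges[label].items():
                assert lo <= lesion.chromophore_concentrations[chromo] <= hi

    def test_unknown_label_rejected(self):
        config = SimulationConfig(frame_shape=(32, 32))
        with pytest.raises(PhantomError):
            synthesize_lesion(config, "keratosis", np.random.default_rng(0))

    def test_degenerate_ranges_give_deterministic_concentrations(self):
        ranges = {cls: {c: (0.5, 0.5) for c in phantom.CHROMOPHORES}
                  for cls in CLASS_NAMES}
        config = SimulationConfig(frame_shape=(32, 32),
                                  class_concentration_ranges=ranges)
        rng = np.random.default_rng(1)
        lesion = synthesize_lesion(config, "nevus", rng)
        assert all(v == 0.5 for v in lesion.chromophore_concentrations.values())


class TestSeparabilityContract:
    """Monte-Carlo check of where the class signal lives in nir_only mode."""

    @staticmethod
    def _mean_reflectance_draws(band_index, n=200):
        config = SimulationConfig(frame_shape=(32, 32),
                                  separability_mode="nir_only", seed=0)
        panel = build_default_chromophore_panel()
        rng = np.random.default_rng(123)
        draws = {}
        for label in CLASS_NAMES:
            vals = [expected_lesion_reflectance(
                synthesize_lesion(config, label, rng), panel)[band_index]
                for _ in range(n)]
            draws[label] = np.array(vals)
        return draws

    def test_visible_band_means_identical_within_noise(self):
        draws = self._mean_reflectance_draws(band_index=3)  # 524 nm
        sds = [d.std() for d in draws.values()]
        means = [d.mean() for d in draws.values()]
        assert max(means) - min(means) < 1.0 * min(sds)

    def test_nir_band_separates_classes_strongly(self):
        draws = self._mean_reflectance_draws(band_index=6)  # 890 nm
        labels = list(draws)
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                da, db = draws[labels[a]], draws[labels[b]]
                pooled_sd = max(da.std(), db.std())
                assert abs(da.mean() - db.mean()) > 2.0 * pooled_sd


class TestRenderCapture:
    def test_noiseless_neutral_frame_is_exact_constant_when_flat(self):
        config = SimulationConfig(
            frame_shape=(16, 16), sensor_noise_sd=0.0, dark_noise_sd=0.0,
            illumination_curvature=(0.0, 0.0, 0.0), seed=0)
        panel = build_default_chromophore_panel()
        lesion = synthesize_lesion(config, "nevus", np.random.default_rng(0))
        cap = render_capture(lesion, panel, config, np.random.default_rng(0))
        amp = phantom._band_amplitude(config,
                                      phantom.background_reflectance(config.bands))
        expected = np.rint(config.dark_offset_mean
                           + amp * config.neutral_reflectance_k)
        assert np.all(cap.neutral_frames == expected)

    def test_melanoma_interior_darker_than_background_at_414(self):
        config = SimulationConfig(frame_shape=(32, 32), sensor_noise_sd=0.0,
                                  dark_noise_sd=0.0)
        panel = build_default_chromophore_panel()
        rng = np.random.default_rng(7)
        lesion = synthesize_lesion(config, "melanoma", rng)
        cap = render_capture(lesion, panel, config, rng)
        inside = cap.lesion_frames[0][cap.lesion_mask]
        outside = cap.lesion_frames[0][~cap.lesion_mask]
        assert inside.mean() < outside.mean()

    def test_saturation_raises(self):
        config = SimulationConfig(frame_shape=(16, 16), illumination_gain=4.0)
        panel = build_default_chromophore_panel()
        rng = np.random.default_rng(0)
        lesion = synthesize_lesion(config, "nevus", rng)
        with pytest.raises(PhantomError, match="saturated"):
            render_capture(lesion, panel, config, rng)


class TestSimulateDataset:
    def test_counts_and_labels(self):
        config = SimulationConfig(
            frame_shape=(16, 16),
            class_counts={"nevus": 2, "melanoma": 2, "bcc": 2}, seed=4)
        captures = simulate_dataset(config)
        assert len(captures) == 6
        labels = [c.true_label for c in captures]
        assert all(labels.count(cls) == 2 for cls in CLASS_NAMES)

    def test_default_cohort_has_509_captures(self):
        """The default class counts (327 nevi, 112 melanomas, 70 BCCs) render
        509 capture sets; small frames keep this a desk-scale check."""
        config = SimulationConfig(frame_shape=(16, 16), store_truth=False,
                                  seed=1)
        captures = simulate_dataset(config)
        assert len(captures) == 509
        labels = [c.true_label for c in captures]
        assert (labels.count("nevus"), labels.count("melanoma"),
                labels.count("bcc")) == (327, 112, 70)

    def test_same_seed_is_bit_identical(self):
        config = dict(frame_shape=(16, 16),
                      class_counts={"nevus": 2, "melanoma": 1, "bcc": 1}, seed=9)
        a = simulate_dataset(SimulationConfig(**config))
        b = simulate_dataset(SimulationConfig(**config))
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.lesion_frames, cb.lesion_frames)
            assert np.array_equal(ca.dark_frames, cb.dark_frames)
            assert np.array_equal(ca.neutral_frames, cb.neutral_frames)

    def test_frames_respect_bit_range_and_dark_statistics(self):
        config = SimulationConfig(
            frame_shape=(32, 32),
            class_counts={"nevus": 2, "melanoma": 1, "bcc": 1}, seed=2)
        for cap in simulate_dataset(config):
            for frames in (cap.lesion_frames, cap.dark_frames, cap.neutral_frames):
                assert frames.max() <= config.max_count
            n = cap.dark_frames[0].size
            tol = 3 * config.dark_noise_sd / np.sqrt(n)
            assert abs(cap.dark_frames.mean() - config.dark_offset_mean) \
                < tol + 0.05  # rounding of counts adds sub-tolerance bias

    def test_positive_class_counts_required(self):
        with pytest.raises(PhantomError):
            simulate_dataset(SimulationConfig(
                frame_shape=(16, 16), class_counts={"nevus": 0, "melanoma": 1,
                                                    "bcc": 1}))


def test_capture_png_roundtrip(tmp_path, noiseless_captures):
    cap = noiseless_captures[0]
    out = write_capture(cap, tmp_path / "cap0")
    back = read_capture(out)
    assert np.array_equal(back.lesion_frames, cap.lesion_frames)
    assert np.array_equal(back.neutral_frames, cap.neutral_frames)
    assert back.true_label == cap.true_label
    assert back.wavelengths_nm == cap.wavelengths_nm
    assert back.bit_depth == cap.bit_depth
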