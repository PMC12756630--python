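"""Masking, filter bank, regional maxima, H-Max, end-to-end detection."""

import warnings

import numpy as np
import pytest

from exotrack.detection import (
    DetectionConfig,
    apply_mask,
    detect_particles,
    filter_bank,
    hmax_suppress,
    regional_maxima,
)
from exotrack.preprocessing import wiener_denoise
from exotrack.synthetic import (
    NoiseMix,
    random_scene,
    rasterize_circles,
    render_scene,
)
from oracles import plateau_maxima_oracle


class TestApplyMask:
    def test_identity_and_annihilating_masks(self, rng):
        frame = rng.random((16, 16))
        assert np.array_equal(apply_mask(frame, np.ones_like(frame, bool)),
                              frame)
        assert not apply_mask(frame, np.zeros_like(frame, bool)).any()

    def test_pixelwise_product_oracle(self, rng):
        frame = rng.random((16, 16))
        mask = rng.random((16, 16)) < 0.5
        out = apply_mask(frame, mask)
        assert all(
            out[i, j] == frame[i, j] * mask[i, j]
            for i in range(16) for j in range(16)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(np.zeros((8, 8)), np.zeros((9, 9), bool))


class TestFilterBank:
    def test_constant_frame_is_fixed_point(self):
        frame = np.full((32, 32), 0.4)
        assert np.allclose(filter_bank(frame), frame)

    def test_equals_composition_of_single_filters(self, rng):
        from scipy.ndimage import gaussian_filter
        cfg = DetectionConfig()
        frame = rng.random((32, 32))
        w = wiener_denoise(frame, cfg.wiener_window)
        s = w + cfg.sharpen_amount * (
            w - gaussian_filter(w, cfg.sharpen_sigma, mode="reflect"))
        g = np.clip(gaussian_filter(s, cfg.gaussian_sigma, mode="reflect"),
                    0, 1)
        assert np.allclose(filter_bank(frame, cfg), g)

    def test_noiseless_scene_one_maximum_inside_each_disc(self,
                                                          noiseless_scene):
        frame = rasterize_circles(noiseless_scene)
        out = filter_bank(frame)
        found = regional_maxima(hmax_suppress(out, 0.05))
        assert len(found) == noiseless_scene.true_count
        for y, x in found.positions:
            assert any(
                (y - c.center_y) ** 2 + (x - c.center_x) ** 2 <= c.radius**2
                for c in noiseless_scene.circles
            )


class TestRegionalMaxima:
    def test_single_strict_peak(self):
        frame = np.zeros((9, 9))
        frame[4, 5] = 1.0
        found = regional_maxima(frame)
        assert [tuple(p) for p in found.positions] == [(4, 5)]

    def test_plateau_yields_single_centroid_representative(self):
        frame = np.zeros((10, 10))
        frame[4:6, 4:6] = 1.0  # 2×2 plateau, centroid (4.5, 4.5) rounds down
        found = regional_maxima(frame)
        assert [tuple(p) for p in found.positions] == [(4, 4)]

    def test_matches_flood_fill_oracle_on_random_frames(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            frame = rng.integers(0, 5, (32, 32)).astype(float)
            found = regional_maxima(frame)
            assert set(map(tuple, found.positions)) == \
                plateau_maxima_oracle(frame)

    def test_nonfinite_frame_rejected(self):
        frame = np.zeros((8, 8))
        frame[0, 0] = np.nan
        with pytest.raises(ValueError):
            regional_maxima(frame)


class TestHMax:
    def test_suppresses_shallow_peak_keeps_tall_one(self):
        frame = np.zeros((20, 20))
        frame[5, 5] = 0.9
        frame[14, 14] = 0.3
        out = hmax_suppress(frame, 0.5)
        found = regional_maxima(out)
        assert [tuple(p) for p in found.positions] == [(5, 5)]

    def test_subthreshold_h_leaves_maxima_unchanged(self):
        frame = np.zeros((20, 20))
        frame[5, 5] = 0.9
        frame[14, 14] = 0.3
        before = set(map(tuple, regional_maxima(frame).positions))
        after = set(map(tuple,
                        regional_maxima(hmax_suppress(frame, 0.05)).positions))
        assert before == after

    def test_reconstruction_bounds(self, rng):
        for _ in range(20):
            frame = rng.random((24, 24))
            h = float(rng.uniform(0.01, 0.5))
            out = hmax_suppress(frame, h)
            diff = frame - out
            assert diff.min() >= -1e-12
            assert diff.max() <= h + 1e-12

    def test_h_at_dynamic_range_warns(self):
        with pytest.warns(UserWarning, match="suppressed"):
            hmax_suppress(np.linspace(0, 0.5, 64).reshape(8, 8), 0.9)


class TestDetectParticles:
    def test_noiseless_scene_exact_count_inside_discs(self, noiseless_scene):
        frame = rasterize_circles(noiseless_scene)
        found = detect_particles(frame[None])[0]
        assert len(found) == noiseless_scene.true_count
        for y, x in found.positions:
            assert any(
                (y - c.center_y) ** 2 + (x - c.center_x) ** 2 <= c.radius**2
                for c in noiseless_scene.circles
            )

    def test_noisy_scenes_mean_absolute_count_error_below_one(self):
        errors = []
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            spec = random_scene((128, 128), 10, (3, 6), rng,
                                noise=NoiseMix(w1=0.2, w2=0.2, seed=seed))
            found = detect_particles(render_scene(spec)[None])[0]
            errors.append(abs(len(found) - spec.true_count))
        assert np.mean(errors) <= 1.0

    def test_hmax_corrects_over_segmentation(self):
        spec = random_scene((128, 128), 5, (4, 6), np.random.default_rng(7),
                            noise=NoiseMix(w1=0.25, w2=0.25, seed=7))
        frame = render_scene(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_off = len(detect_particles(
                frame[None], det=DetectionConfig(hmax_enabled=False))[0])
        n_on = len(detect_particles(frame[None])[0])
        assert n_off > spec.true_count  # fragmented without suppression
        assert abs(n_on - spec.true_count) < abs(n_off - spec.true_count)

    def test_count_invariant_under_affine_intensity_rescale(self):
        spec = random_scene((128, 128), 8, (3, 6), np.random.default_rng(4),
                            noise=NoiseMix(w1=0.2, w2=0.2, seed=4))
        frame = render_scene(spec)
        a = detect_particles(frame[None])[0]
        b = detect_particles((0.3 * frame + 0.2)[None])[0]
        assert len(a) == len(b)

    def test_empty_frame_warns_and_returns_no_detections(self):
        with pytest.warns(UserWarning, match="empty refined mask"):
            found = detect_particles(np.zeros((1, 128, 128)))[0]
        assert len(found) == 0

    def test_invalid_hmax_h_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(hmax_h=1.5)
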