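import numpy as np
import pytest

from cepquant import AnalysisConfig, PhantomSpec, render
from cepquant.cropping import crop_dendrites
from cepquant.features import (detect_features, enhance, erode_seeds,
                               min_max_caliper, region_descriptors,
                               threshold_dendrites)
from cepquant.phantom import BlebRecord

from conftest import gaussian_ridge, make_roi


def _enhanced_from(pixels01, **kw):
    return enhance(make_roi(pixels01, **kw))


class TestEnhance:
    def test_dimensions_are_4x(self):
        roi = make_roi(gaussian_ridge((200, 80), [40], 3.4))
        eroi = enhance(roi)
        assert eroi.pixels.shape == (800, 320)
        assert eroi.scale.resize_factor == 4

    def test_flat_background_near_zero_after_subtraction(self):
        eroi = _enhanced_from(gaussian_ridge((200, 80), [40], 3.4))
        border = np.concatenate([eroi.pixels[:, :40].ravel(),
                                 eroi.pixels[:, -40:].ravel()])
        assert np.median(border) < 0.02

    def test_illumination_gradient_suppressed(self):
        base = gaussian_ridge((200, 80), [40], 3.4)
        ramped = base + np.linspace(0, 0.2, 200)[:, None]
        flat_bg = enhance(make_roi(base)).pixels[:, 5:20].mean(axis=1)
        ramp_bg = enhance(make_roi(ramped)).pixels[:, 5:20].mean(axis=1)
        in_slope = 0.2 / 200 / 4  # per enhanced row
        out_slope = abs(np.polyfit(np.arange(len(ramp_bg)), ramp_bg - flat_bg, 1)[0])
        assert out_slope <= in_slope / 10

    def test_noise_level_recorded_nonnegative(self):
        eroi = _enhanced_from(gaussian_ridge((200, 80), [40], 3.4))
        assert eroi.noise_level >= 0


class TestThreshold:
    def test_noiseless_foreground_hugs_dendrite(self):
        eroi = _enhanced_from(gaussian_ridge((200, 80), [40], 3.4))
        mask = threshold_dendrites(eroi)
        cols = np.flatnonzero(mask.any(axis=0))
        assert 120 < cols.mean() < 200  # centered on the ridge at col 40*4

    def test_noisy_false_positives_bounded(self):
        rng = np.random.default_rng(42)
        img = gaussian_ridge((200, 80), [40], 3.4)
        noisy = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
        eroi = _enhanced_from(noisy)
        mask = threshold_dendrites(eroi)
        off_ridge = mask.copy()
        off_ridge[:, 100:220] = False  # exclude the true dendrite band
        assert off_ridge.mean() <= 0.01


class TestErodeSeeds:
    def _mask_with_blebs(self, bleb_specs):
        spec = PhantomSpec(blebs=tuple(bleb_specs), seed=30)
        img, truth = render(spec)
        roi, _ = crop_dendrites(img)
        eroi = enhance(roi)
        return erode_seeds(threshold_dendrites(eroi), eroi.scale), eroi, truth, roi

    def test_bleb_free_dendrites_yield_no_seeds(self):
        seeds, *_ = self._mask_with_blebs([])
        assert seeds == []

    def test_single_bleb_single_seed_within_1um(self):
        seeds, eroi, truth, roi = self._mask_with_blebs([BlebRecord(2, 0.5, 2.5)])
        assert len(seeds) == 1
        eff = eroi.scale.effective
        cx = seeds[0].centroid[1] * eff
        _, tx = truth.bleb_positions_um[1][0]
        # truth x is in source-frame um; the ROI shifts columns by the crop
        _, c_off = roi.transform["crop"]
        assert abs(cx - (tx - c_off * 0.1)) <= 1.0

    def test_two_blebs_two_seeds(self):
        seeds, *_ = self._mask_with_blebs(
            [BlebRecord(2, 0.4, 2.5), BlebRecord(2, 0.65, 2.5)])  # 10 um apart
        assert len(seeds) == 2


class TestRefinement:
    def test_disk_feature_round_and_area_accurate(self):
        """A hard disk 2.5 um across refines to a near-circular region of
        matching area."""
        img = np.full((200, 120), 0.03)
        yy, xx = np.mgrid[:200, :120]
        img[(yy - 100) ** 2 + (xx - 60) ** 2 <= 12.5**2] = 0.6  # r=1.25um
        feats = detect_features(_enhanced_from(img))
        assert len(feats) == 1
        true_area = np.pi * 1.25**2
        assert feats[0].area_um2 == pytest.approx(true_area, rel=0.15)
        assert feats[0].circularity >= 0.8

    def test_rectangle_extent_is_one(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[10:50, 20:70] = True
        eroi = _enhanced_from(np.full((100, 100), 0.03))
        feat = region_descriptors(mask, (0, 0), eroi)
        assert feat.extent == 1.0

    def test_cross_extent_low(self):
        mask = np.zeros((90, 90), dtype=bool)
        mask[40:50, 5:85] = True
        mask[5:85, 40:50] = True
        eroi = _enhanced_from(np.full((100, 100), 0.03))
        feat = region_descriptors(mask, (0, 0), eroi)
        assert feat.extent <= 0.4

    def test_caliper_ordering_and_extent_bounds(self):
        img, _ = render(PhantomSpec(
            blebs=tuple(BlebRecord(1, p, 2.5) for p in (0.3, 0.7)), seed=31))
        roi, _ = crop_dendrites(img)
        for f in detect_features(enhance(roi)):
            assert f.min_caliper_um <= f.max_caliper_um
            assert 0.0 <= f.extent <= 1.0
            assert 0.0 <= f.eccentricity < 1.0


class TestCalipers:
    def test_square_calipers(self):
        coords = np.array([(r, c) for r in range(10) for c in range(10)])
        mn, mx = min_max_caliper(coords)
        assert mn == pytest.approx(10.0, abs=0.01)
        assert mx == pytest.approx(10 * np.sqrt(2), abs=0.01)

    def test_line_calipers(self):
        coords = np.array([(0, c) for c in range(20)])
        mn, mx = min_max_caliper(coords)
        assert mn == pytest.approx(1.0, abs=0.01)
        assert mx >= 20.0


class TestPhysicalInvariance:
    def test_feature_count_invariant_across_pixel_sizes(self):
        blebs = tuple(BlebRecord(2, p, 2.5) for p in (0.3, 0.7))
        counts = {}
        for px, size in [(0.1, (560, 320)), (0.2, (280, 160))]:
            img, _ = render(PhantomSpec(pixel_size=px, image_size=size,
                                        blebs=blebs, seed=32))
            roi, _ = crop_dendrites(img)
            counts[px] = len(detect_features(enhance(roi)))
        assert counts[0.1] == counts[0.2] == 2

    def test_adding_bleb_never_decreases_seeds(self):
        counts = []
        for blebs in ([], [BlebRecord(2, 0.5, 2.5)],
                      [BlebRecord(2, 0.5, 2.5), BlebRecord(3, 0.4, 2.5)]):
            img, _ = render(PhantomSpec(blebs=tuple(blebs), seed=30))
            roi, _ = crop_dendrites(img)
            eroi = enhance(roi)
            counts.append(len(erode_seeds(threshold_dendrites(eroi), eroi.scale)))
        assert counts == sorted(counts)
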