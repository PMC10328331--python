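import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cepquant import AnalysisConfig, PhantomSpec, PixelScale, render
from cepquant.cropping import crop_dendrites
from cepquant.features import BlebFeature, enhance
from cepquant.metrics import (binarize_for_breaks, compute_report,
                              detect_breaks, match_features,
                              score_from_values)
from cepquant.phantom import BreakRecord
from cepquant.pipeline import analyze_projection
from cepquant.tracking import DendriteTrack, track_dendrites


def straight_track(index=1, n_rows=400, col=100.0,
                   scale=PixelScale(0.1, resize_factor=4)):
    x = np.full(n_rows, col)
    det = np.ones(n_rows, dtype=bool)
    return DendriteTrack(index, x, det, scale, span=(0, n_rows - 1))


class TestScoring:
    @pytest.mark.parametrize("pct,count,expected", [
        (100.0, 0, 0),
        (100.0, 3, 1), (100.0, 4, 1),
        (100.0, 5, 2), (100.0, 8, 2),
        (85.0, 0, 3), (70.0, 0, 3), (70.0, 10, 3), (50.0, 0, 3),
        (49.9, 0, 4), (30.0, 10, 4), (0.0, 0, 4),
        (86.0, 0, 0),
    ])
    def test_bins(self, pct, count, expected):
        assert score_from_values(pct, count) == expected

    @settings(max_examples=200, derandomize=True)
    @given(pct=st.floats(0, 100), count=st.integers(0, 50))
    def test_total_and_in_range(self, pct, count):
        assert score_from_values(pct, count) in (0, 1, 2, 3, 4)

    @settings(max_examples=100, derandomize=True)
    @given(pct=st.floats(85.01, 100), c1=st.integers(0, 20), c2=st.integers(0, 20))
    def test_monotone_in_feature_count_without_breaks(self, pct, c1, c2):
        lo, hi = sorted((c1, c2))
        assert score_from_values(pct, lo) <= score_from_values(pct, hi)

    @settings(max_examples=100, derandomize=True)
    @given(p1=st.floats(0, 100), p2=st.floats(0, 100))
    def test_breakage_branch_monotone(self, p1, p2):
        lo, hi = sorted((p1, p2))
        s_lo, s_hi = score_from_values(lo, 0), score_from_values(hi, 0)
        assert s_lo >= s_hi


class TestDetectBreaks:
    def test_intact_track_no_breaks(self):
        mask = np.zeros((400, 200), dtype=bool)
        mask[:, 95:106] = True
        assert detect_breaks(straight_track(), mask) == []

    def test_single_gap_measured(self):
        mask = np.zeros((400, 200), dtype=bool)
        mask[:, 95:106] = True
        mask[100:300, :] = False  # 5 um gap on the 0.025 grid
        breaks = detect_breaks(straight_track(), mask)
        assert len(breaks) == 1
        assert breaks[0].length_um == pytest.approx(5.0, abs=1.0)

    def test_two_gaps_total(self):
        mask = np.zeros((800, 200), dtype=bool)
        mask[:, 95:106] = True
        mask[100:220, :] = False   # 3 um
        mask[400:720, :] = False   # 8 um
        breaks = detect_breaks(straight_track(n_rows=800), mask)
        assert len(breaks) == 2
        assert sum(b.length_um for b in breaks) == pytest.approx(11.0, abs=1.5)

    def test_subminimum_dropouts_ignored(self):
        mask = np.zeros((400, 200), dtype=bool)
        mask[:, 95:106] = True
        mask[200:210, :] = False  # 0.25 um: below the minimum break length
        assert detect_breaks(straight_track(), mask) == []

    def test_empty_mask_one_full_break(self):
        mask = np.zeros((400, 200), dtype=bool)
        breaks = detect_breaks(straight_track(), mask)
        assert len(breaks) == 1
        assert breaks[0].length_um == pytest.approx(10.0, abs=0.2)


class TestMatchFeatures:
    @staticmethod
    def _tracks():
        return [straight_track(1, col=60.0), straight_track(2, col=140.0)]

    def _feature(self, x_um):
        return BlebFeature((5.0, x_um), 1.0, 1.0, 1.0, 1.0, 0.5, 1.0, 1.0, 100.0)

    def test_nearest_track_wins(self):
        feats = match_features([self._feature(3.0)], self._tracks())
        assert feats[0].dendrite_index == 2  # 140 px * 0.025 = 3.5 um

    def test_equidistant_goes_to_lower_index(self):
        feats = match_features([self._feature(2.5)], self._tracks())
        assert feats[0].dendrite_index == 1

    def test_far_feature_unassigned(self):
        feats = match_features([self._feature(20.0)], self._tracks())
        assert feats[0].dendrite_index == 0


class TestComputeReport:
    def _roi(self):
        from conftest import make_roi
        return make_roi(np.full((100, 50), 0.2))

    def test_percent_remaining_arithmetic(self):
        track = straight_track(n_rows=1600)  # 40 um
        mask = np.ones((1600, 200), dtype=bool)
        mask[400:800, :] = False             # 10 um break
        breaks = detect_breaks(track, mask)
        report = compute_report(self._roi(), track, breaks, [])
        assert report.percent_remaining == pytest.approx(75.0, abs=1.0)
        assert report.break_count == 1

    def test_conservation(self):
        track = straight_track(n_rows=1600)
        mask = np.ones((1600, 200), dtype=bool)
        mask[100:500, :] = False
        mask[900:1100, :] = False
        report = compute_report(self._roi(), track,
                                detect_breaks(track, mask), [])
        assert (report.total_break_length_um + report.remaining_length_um
                == pytest.approx(report.dendrite_length_um, abs=0.05))

    def test_features_per_length(self):
        track = straight_track(n_rows=2400)  # 60 um intact
        mask = np.ones((2400, 200), dtype=bool)
        feats = [BlebFeature((y, 2.5), 1.0, 1.0, 1.0, 1.0, 0.5, 1.0, 1.0, 100.0,
                             dendrite_index=1) for y in (10.0, 30.0, 50.0)]
        report = compute_report(self._roi(), track, [], feats)
        assert report.feature_count == 3
        assert report.features_per_length == pytest.approx(0.05, rel=0.01)
        assert report.features_per_remaining == pytest.approx(0.05, rel=0.01)

    def test_normalized_location_convention(self):
        """0 at the proximal (bottom) end, 1 at the distal tip."""
        track = straight_track(n_rows=1600)
        mask = np.ones((1600, 200), dtype=bool)

        def loc_of(y_um):
            f = BlebFeature((y_um, 2.5), 1.0, 1.0, 1.0, 1.0, 0.5, 1.0, 1.0,
                            100.0, dendrite_index=1)
            return compute_report(self._roi(), track, [], [f]
                                  ).mean_normalized_feature_location

        assert loc_of(39.5) == pytest.approx(0.0, abs=0.05)   # near bottom
        assert loc_of(0.5) == pytest.approx(1.0, abs=0.05)    # near top

    def test_null_coding_without_features(self):
        track = straight_track(n_rows=1600)
        report = compute_report(self._roi(), track, [], [])
        assert report.feature_count == 0
        assert math.isnan(report.mean_feature_area_um2)
        assert math.isnan(report.mean_normalized_feature_location)

    def test_short_track_flagged_unreliable(self):
        track = straight_track(n_rows=100)  # 2.5 um
        report = compute_report(self._roi(), track, [], [])
        assert report.unreliable


class TestBreakOracle:
    """Break detection must agree with a naive per-row scan."""

    @staticmethod
    def brute_force(track, mask, config):
        eff = track.scale.effective
        tol = max(1, int(round(track.scale.to_px(config.lateral_probe_um))))
        miss_rows = []
        for r in range(track.span[0], track.span[1] + 1):
            c = int(round(track.x_of_y[r]))
            lo, hi = max(0, c - tol), min(mask.shape[1], c + tol + 1)
            if not (lo < hi and mask[r, lo:hi].any()):
                miss_rows.append(r)
        # group contiguous misses without run-length machinery
        groups, cur = [], []
        for r in miss_rows:
            if cur and r != cur[-1] + 1:
                groups.append(cur)
                cur = []
            cur.append(r)
        if cur:
            groups.append(cur)
        min_rows = max(1, int(round(track.scale.to_px(config.min_break_length_um))))
        return [(g[0], g[-1] + 1) for g in groups if len(g) >= min_rows]

    def test_agreement_on_seeded_phantom_masks(self):
        config = AnalysisConfig()
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_breaks = rng.integers(0, 3)
            breaks = []
            start = 0.05
            for _ in range(n_breaks):
                length = rng.uniform(3, 12)
                frac = length / 40.0
                s = rng.uniform(start, min(0.95 - frac, start + 0.3))
                breaks.append(BreakRecord(1, s, length))
                start = s + frac + 0.05
            img, truth = render(PhantomSpec(breaks=tuple(breaks),
                                            seed=int(rng.integers(1 << 30))))
            mask = img.pixels > 0.15 * img.pixels.max()
            line = truth.centerlines_um[0] / 0.1
            rows = np.round(line[:, 0]).astype(int)
            x = np.full(img.pixels.shape[0], np.nan)
            x[rows] = line[:, 1]
            track = DendriteTrack(1, x, ~np.isnan(x), PixelScale(0.1),
                                  span=(rows.min(), rows.max()))
            got = [(int(round(b.y_start_um / 0.1)), int(round(b.y_end_um / 0.1)))
                   for b in detect_breaks(track, mask, config)]
            assert got == self.brute_force(track, mask, config)


class TestEndToEndRecovery:
    def test_break_recovered_within_tolerance(self):
        img, truth = render(PhantomSpec(breaks=(BreakRecord(3, 0.4, 10.0),),
                                        seed=66))
        reports = analyze_projection(img)
        r = next(r for r in reports if r.dendrite_index == 3)
        assert abs(r.percent_remaining - truth.percent_remaining[2]) <= 5.0
        assert r.break_count == 1
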