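"""Break detection, feature matching, the 20-metric report, and scoring.

A break is a span of a tracked dendrite with no detectable fluorescence:
each row of a finalized track is probed against a permissive binarization
of the dendrites, and maximal runs of signal-free rows longer than the
minimum break length become break segments. Percent dendrite remaining
and feature count per length are the two metrics that normalize out
animal-to-animal length differences.

The continuous report is finally collapsed onto the conventional 0-4
categorical degeneration score. Breakage takes precedence over blebbing:
any dendrite with less than half its length remaining scores 4, one with
50-85% remaining scores 3, and only dendrites above 85% remaining are
scored by bleb count (0: none, 1: fewer than five, 2: five or more).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .config import AnalysisConfig
from .cropping import DendriteROI
from .features import BlebFeature, EnhancedROI, threshold_value
from .tracking import DendriteTrack

__all__ = ["BreakSegment", "DendriteReport", "METRIC_COLUMNS",
           "binarize_for_breaks", "detect_breaks", "match_features",
           "compute_report", "categorical_score", "score_from_values",
           "reports_to_frame"]

#: The canonical 20-metric schema, in report column order.
METRIC_COLUMNS = [
    "dendrite_length_um",
    "remaining_length_um",
    "percent_remaining",
    "break_count",
    "total_break_length_um",
    "largest_break_length_um",
    "mean_dendrite_intensity",
    "feature_count",
    "features_per_length",
    "features_per_remaining",
    "mean_feature_intensity",
    "total_feature_area_um2",
    "mean_feature_area_um2",
    "mean_feature_perimeter_um",
    "mean_feature_circularity",
    "mean_feature_extent",
    "mean_feature_eccentricity",
    "mean_min_caliper_um",
    "mean_max_caliper_um",
    "mean_normalized_feature_location",
]


@dataclass
class BreakSegment:
    """A signal-free span of one dendrite track (ROI coordinates, um)."""

    dendrite_index: int
    y_start_um: float
    y_end_um: float
    length_um: float            # arc length of the track over the gap rows


@dataclass
class DendriteReport:
    """The 20-metric record for one dendrite plus its categorical score."""

    image: str
    dendrite_index: int
    dendrite_length_um: float
    remaining_length_um: float
    percent_remaining: float
    break_count: int
    total_break_length_um: float
    largest_break_length_um: float
    mean_dendrite_intensity: float
    feature_count: int
    features_per_length: float
    features_per_remaining: float
    mean_feature_intensity: float = math.nan
    total_feature_area_um2: float = math.nan
    mean_feature_area_um2: float = math.nan
    mean_feature_perimeter_um: float = math.nan
    mean_feature_circularity: float = math.nan
    mean_feature_extent: float = math.nan
    mean_feature_eccentricity: float = math.nan
    mean_min_caliper_um: float = math.nan
    mean_max_caliper_um: float = math.nan
    mean_normalized_feature_location: float = math.nan
    categorical_score: int = 0
    unreliable: bool = False


def reports_to_frame(reports: list[DendriteReport]) -> pd.DataFrame:
    """Tabulate reports: identifiers, the 20 metrics in order, score last."""
    cols = (["image", "dendrite_index"] + METRIC_COLUMNS
            + ["categorical_score", "unreliable"])
    rows = [{f.name: getattr(r, f.name) for f in fields(DendriteReport)}
            for r in reports]
    return pd.DataFrame(rows, columns=cols)


def binarize_for_breaks(eroi: EnhancedROI,
                        config: AnalysisConfig | None = None) -> np.ndarray:
    """Permissive dendrite binarization answering "is there signal here?".

    Uses a fraction of the feature-detection threshold so that dim but
    intact dendrite stretches are not scored as broken. An empty mask is
    a valid outcome (a fully lost dendrite), never an error.
    """
    config = config or AnalysisConfig()
    if eroi.pixels.max() <= eroi.pixels.min():
        return np.zeros(eroi.pixels.shape, dtype=bool)
    thr = config.break_threshold_fraction * threshold_value(eroi, config)
    return eroi.pixels > thr


def detect_breaks(track: DendriteTrack, mask: np.ndarray,
                  config: AnalysisConfig | None = None) -> list[BreakSegment]:
    """Find maximal signal-free runs along one finalized track.

    Each row in the track's span probes the mask within a lateral
    tolerance of the track position; runs of miss-rows at least the
    minimum break length long become segments. Segment length is the arc
    length of the track across the gap, so break lengths and the
    remaining length always add up to the full dendrite length.
    """
    config = config or AnalysisConfig()
    eff = track.scale.effective
    tol = max(1, int(round(track.scale.to_px(config.lateral_probe_um))))
    r0, r1 = track.span
    w = mask.shape[1]
    hits = np.ones(r1 - r0 + 1, dtype=bool)
    for i, r in enumerate(range(r0, r1 + 1)):
        c = int(round(track.x_of_y[r]))
        lo, hi = max(0, c - tol), min(w, c + tol + 1)
        hits[i] = bool(mask[r, lo:hi].any()) if lo < hi else False

    min_rows = max(1, int(round(track.scale.to_px(config.min_break_length_um))))
    segments: list[BreakSegment] = []
    i = 0
    n = len(hits)
    while i < n:
        if not hits[i]:
            j = i
            while j < n and not hits[j]:
                j += 1
            if j - i >= min_rows:
                rows = np.arange(r0 + i, r0 + j)
                length = track.arc_length_um(rows) if len(rows) > 1 else eff
                segments.append(BreakSegment(track.index, (r0 + i) * eff,
                                             (r0 + j) * eff, length))
            i = j
        else:
            i += 1
    return segments


def match_features(features: list[BlebFeature], tracks: list[DendriteTrack],
                   config: AnalysisConfig | None = None) -> list[BlebFeature]:
    """Assign each feature to the laterally nearest track within a gate.

    Features farther than the gate from every track stay unassigned
    (index 0) and are excluded from per-dendrite aggregates. Equidistant
    ties go to the lower index.
    """
    config = config or AnalysisConfig()
    for f in features:
        fy, fx = f.centroid_um
        best, best_d = 0, math.inf
        for tr in tracks:
            eff = tr.scale.effective
            r = int(round(fy / eff))
            r = min(max(r, tr.span[0]), tr.span[1])
            d = abs(fx - tr.x_of_y[r] * eff)
            if d < best_d:  # strict <, so ties keep the lower index
                best, best_d = tr.index, d
        f.dendrite_index = best if best_d <= config.feature_gate_um else 0
    return features


def _track_intensity(track: DendriteTrack, roi: DendriteROI,
                     break_rows: np.ndarray) -> float:
    """Mean native-unit intensity along the track's non-break rows."""
    r0, r1 = track.span
    rows = np.arange(r0, r1 + 1)
    rows = rows[~np.isin(rows, break_rows)]
    if rows.size == 0:
        return math.nan
    factor = track.scale.resize_factor // roi.scale.resize_factor
    coords = np.vstack([rows / factor, track.x_of_y[rows] / factor])
    vals = map_coordinates(roi.pixels.astype(float), coords, order=1,
                           mode="nearest")
    return float(vals.mean())


def compute_report(roi: DendriteROI, track: DendriteTrack,
                   breaks: list[BreakSegment], features: list[BlebFeature],
                   image: str = "", config: AnalysisConfig | None = None
                   ) -> DendriteReport:
    """Assemble the 20-metric record for one dendrite.

    Lengths are track arc lengths in um. The normalized feature location
    runs from 0 at the proximal (cell-body) end to 1 at the distal tip.
    Feature aggregates cover only the features matched to this dendrite
    and are null-coded (NaN) when there are none; counts stay 0.
    """
    config = config or AnalysisConfig()
    eff = track.scale.effective
    length = track.arc_length_um()
    total_break = sum(b.length_um for b in breaks)
    total_break = min(total_break, length)
    remaining = length - total_break
    pct = 100.0 * remaining / length if length > 0 else 0.0

    break_rows = np.concatenate([
        np.arange(int(round(b.y_start_um / eff)), int(round(b.y_end_um / eff)))
        for b in breaks]) if breaks else np.array([], dtype=int)
    mean_int = _track_intensity(track, roi, break_rows)

    mine = [f for f in features if f.dendrite_index == track.index]
    n = len(mine)
    report = DendriteReport(
        image=image,
        dendrite_index=track.index,
        dendrite_length_um=length,
        remaining_length_um=remaining,
        percent_remaining=pct,
        break_count=len(breaks),
        total_break_length_um=total_break,
        largest_break_length_um=max((b.length_um for b in breaks), default=0.0),
        mean_dendrite_intensity=mean_int,
        feature_count=n,
        features_per_length=n / length if length > 0 else math.nan,
        features_per_remaining=n / remaining if remaining > 0 else math.nan,
        unreliable=length < config.min_reliable_length_um,
    )
    if n:
        r0, r1 = track.span
        # cumulative arc length measured from the proximal (bottom) end
        rows = np.arange(r0, r1 + 1)
        x = track.x_of_y[rows]
        seg = np.sqrt(np.diff(rows.astype(float)) ** 2 + np.diff(x) ** 2) * eff
        cum_from_top = np.concatenate([[0.0], np.cumsum(seg)])
        locations = []
        for f in mine:
            r = int(round(f.centroid_um[0] / eff))
            r = min(max(r, r0), r1)
            dist_from_proximal = cum_from_top[-1] - cum_from_top[r - r0]
            locations.append(dist_from_proximal / length if length > 0 else 0.0)
        report.mean_feature_intensity = float(np.mean([f.mean_intensity for f in mine]))
        report.total_feature_area_um2 = float(sum(f.area_um2 for f in mine))
        report.mean_feature_area_um2 = float(np.mean([f.area_um2 for f in mine]))
        report.mean_feature_perimeter_um = float(np.mean([f.perimeter_um for f in mine]))
        report.mean_feature_circularity = float(np.mean([f.circularity for f in mine]))
        report.mean_feature_extent = float(np.mean([f.extent for f in mine]))
        report.mean_feature_eccentricity = float(np.mean([f.eccentricity for f in mine]))
        report.mean_min_caliper_um = float(np.mean([f.min_caliper_um for f in mine]))
        report.mean_max_caliper_um = float(np.mean([f.max_caliper_um for f in mine]))
        report.mean_normalized_feature_location = float(np.clip(np.mean(locations), 0.0, 1.0))
    report.categorical_score = categorical_score(report)
    return report


def score_from_values(percent_remaining: float, feature_count: int) -> int:
    """Map (percent remaining, bleb count) onto the 0-4 degeneration score.

    Breakage takes precedence: below 50% remaining scores 4, between 50
    and 85% (inclusive) scores 3. Above 85% remaining, the score is set
    by bleb count alone: none -> 0, fewer than five -> 1, five or more -> 2.
    """
    if percent_remaining < 50.0:
        return 4
    if percent_remaining <= 85.0:
        return 3
    if feature_count == 0:
        return 0
    if feature_count < 5:
        return 1
    return 2


def categorical_score(report: DendriteReport) -> int:
    """The 0-4 degeneration bin of one dendrite report."""
    return score_from_values(report.percent_remaining, report.feature_count)
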