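"""Trace up to four dendrites through breaks and curvature.

Starting at the distal (top) edge, every pixel row of the enhanced image
contributes up to four local intensity maxima — one per dendrite. Rows
crossing a break legitimately contribute fewer. A vertical morphological
closing bridges detection dropouts, skeletonization thins the bridged
columns, and each skeleton point is binned to a dendrite by comparing its
x position against a running (exponential moving) average per dendrite.
Finally each track is interpolated across missing interior rows and
smoothed, yielding at most four discrete tracks ordered left to right.

A deliberate consequence of the forward-only row scan: a track's x is a
function of y, so dendrites that fold back on themselves (>=90 degree
kinks) are interpolated through rather than followed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks
from skimage.measure import label
from skimage.morphology import skeletonize

import logging

from .config import AnalysisConfig, PixelScale
from .features import EnhancedROI, threshold_value

log = logging.getLogger("cepquant")

__all__ = ["DendriteTrack", "row_maxima", "bridge_and_skeletonize",
           "bin_fragments", "finalize_tracks", "track_dendrites"]


@dataclass
class DendriteTrack:
    """Per-row x-position trace of one dendrite on the enhanced grid.

    ``x_of_y[r]`` is the column (effective px) at row ``r``, NaN where the
    dendrite was neither detected nor (yet) interpolated. ``detected[r]``
    stays False on interpolated rows so break detection can tell them
    apart. Rows are ROI-canonical: row 0 is distal, the last row proximal.
    """

    index: int
    x_of_y: np.ndarray
    detected: np.ndarray
    scale: PixelScale
    span: tuple[int, int] = (0, 0)      # (first, last) detected row

    @property
    def span_um(self) -> tuple[float, float]:
        return (self.span[0] * self.scale.effective,
                self.span[1] * self.scale.effective)

    def arc_length_um(self, rows: np.ndarray | None = None) -> float:
        """Polyline arc length over ``rows`` (default: the whole span)."""
        r0, r1 = self.span
        if rows is None:
            rows = np.arange(r0, r1 + 1)
        rows = rows[(rows >= r0) & (rows <= r1)]
        if len(rows) < 2:
            return 0.0
        x = self.x_of_y[rows]
        seg = np.sqrt(np.diff(rows.astype(float)) ** 2 + np.diff(x) ** 2)
        return float(seg.sum() * self.scale.effective)


def row_maxima(eroi: EnhancedROI,
               config: AnalysisConfig | None = None) -> np.ndarray:
    """Mark up to four prominent, well-separated maxima per row.

    Peaks must clear both a prominence floor tied to the recorded noise
    level and the permissive signal threshold used for break detection,
    so rows with nothing but background never contribute track points.
    """
    config = config or AnalysisConfig()
    prominence = max(config.peak_prominence_noise_mult * eroi.noise_level,
                     config.peak_prominence_floor)
    height = config.break_threshold_fraction * threshold_value(eroi, config)
    distance = max(1, int(round(eroi.scale.to_px(config.min_peak_separation_um))))
    grid = np.zeros(eroi.pixels.shape, dtype=bool)
    for r, row in enumerate(eroi.pixels):
        peaks, props = find_peaks(row, prominence=prominence, distance=distance,
                                  height=height)
        if len(peaks) > 4:
            peaks = peaks[np.argsort(row[peaks])[-4:]]
        grid[r, peaks] = True
    return grid


def bridge_and_skeletonize(candidates: np.ndarray, scale: PixelScale,
                           config: AnalysisConfig | None = None) -> np.ndarray:
    """Vertical closing joins same-dendrite runs; skeletonize and label."""
    config = config or AnalysisConfig()
    length = max(1, int(round(scale.to_px(config.vertical_closing_um))))
    # zero-pad so the closing neither extends columns past the frame edge
    # nor erodes genuine run ends
    padded = np.zeros((candidates.shape[0] + 2 * length, candidates.shape[1]),
                      dtype=np.uint8)
    padded[length:-length] = candidates
    closed = maximum_filter1d(padded, size=length, axis=0)
    closed = minimum_filter1d(closed, size=length, axis=0)[length:-length] == 1
    closed |= candidates
    return label(skeletonize(closed), connectivity=2)


def bin_fragments(fragments: np.ndarray, scale: PixelScale,
                  config: AnalysisConfig | None = None) -> list[DendriteTrack]:
    """Assign skeleton points to dendrites via per-dendrite running averages.

    Rows are scanned distal to proximal. A point joins the dendrite whose
    running-average x is nearest within the gating distance; when two
    points claim the same dendrite in one row, the farther one is removed,
    leaving at most four dendrite indices per row (each row supplies at
    most four maxima). Points beyond every gate seed a new candidate only
    in the distal seeding region; if more than four candidates persist,
    the four with the most detected points are kept and a warning logged.
    """
    config = config or AnalysisConfig()
    n_rows = fragments.shape[0]
    gate = scale.to_px(config.gating_distance_um)
    w = config.ema_weight
    seed_limit = int(config.seeding_row_fraction * n_rows)
    # more candidates than dendrites may be seeded (noise, artifacts);
    # the weakest by point count are discarded at the end
    max_candidates = 8

    emas: list[float] = []
    xs = []        # per track: row -> x
    det = []
    for r in range(n_rows):
        cols = np.flatnonzero(fragments[r])
        if cols.size == 0:
            continue
        # greedy nearest assignment, ties to the lower index
        taken: dict[int, float] = {}
        unassigned = []
        for c in cols:
            if emas:
                dists = np.abs(np.array(emas) - c)
                t = int(np.argmin(dists))
                if dists[t] <= gate:
                    if t not in taken or abs(c - emas[t]) < abs(taken[t] - emas[t]):
                        taken[t] = float(c)
                    continue
            unassigned.append(float(c))
        for c in unassigned:
            if len(emas) < max_candidates and r <= seed_limit:
                emas.append(c)
                xs.append(np.full(n_rows, np.nan))
                det.append(np.zeros(n_rows, dtype=bool))
                taken[len(emas) - 1] = c
        for t, c in taken.items():
            emas[t] = (1 - w) * emas[t] + w * c
            xs[t][r] = c
            det[t][r] = True

    order = sorted(range(len(xs)), key=lambda i: int(det[i].sum()), reverse=True)
    if len(order) > 4:
        log.warning("%d candidate dendrite columns; keeping the 4 with most "
                    "evidence", len(order))
    kept = sorted(order[:4])
    return [DendriteTrack(i + 1, xs[t], det[t], scale)
            for i, t in enumerate(kept)]


def _detected_runs(detected: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) spans of consecutive True entries."""
    padded = np.concatenate([[0], detected.astype(np.int8), [0]])
    diff = np.diff(padded)
    return list(zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)))


def finalize_tracks(tracks: list[DendriteTrack],
                    config: AnalysisConfig | None = None) -> list[DendriteTrack]:
    """Interpolate interior gaps, smooth, and re-index left to right.

    Tracks whose summed detected evidence is below the minimum (a few um
    of rows) are dropped: stray noise peaks can seed a track but never
    accumulate the contiguous support a dendrite - even a mostly broken
    one - provides. The detected mask survives finalization so break
    detection can still distinguish observed rows from interpolated ones.
    """
    config = config or AnalysisConfig()
    min_rows = max(2, int(round(tracks[0].scale.to_px(config.min_track_evidence_um)))
                   ) if tracks else 2
    out = []
    for tr in tracks:
        detected = tr.detected.copy()
        # a track end must be backed by a contiguous run of detected rows;
        # stray noise points cannot extend the span past the dendrite tip
        min_run = max(1, int(round(tr.scale.to_px(config.track_end_min_run_um))))
        runs = _detected_runs(detected)
        runs = [(a, b) for a, b in runs if b - a >= min_run]
        if not runs:
            continue
        detected[:runs[0][0]] = False
        detected[runs[-1][1]:] = False
        rows = np.flatnonzero(detected)
        if len(rows) < min_rows:
            continue  # too little evidence to be a dendrite
        tr = DendriteTrack(tr.index, tr.x_of_y, detected, tr.scale)
        r0, r1 = int(rows[0]), int(rows[-1])
        span_rows = np.arange(r0, r1 + 1)
        filled = np.interp(span_rows, rows, tr.x_of_y[rows])
        win = max(1, int(round(tr.scale.to_px(config.smoothing_window_um))))
        filled = uniform_filter1d(filled, size=win, mode="nearest")
        x = np.full_like(tr.x_of_y, np.nan)
        x[span_rows] = filled
        out.append(DendriteTrack(tr.index, x, tr.detected.copy(), tr.scale,
                                 span=(r0, r1)))
    out.sort(key=lambda t: np.nanmean(t.x_of_y))
    for i, tr in enumerate(out):
        tr.index = i + 1
    return out


def track_dendrites(eroi: EnhancedROI,
                    config: AnalysisConfig | None = None) -> list[DendriteTrack]:
    """The full tracking stage: maxima, bridging, binning, finalization."""
    config = config or AnalysisConfig()
    candidates = row_maxima(eroi, config)
    fragments = bridge_and_skeletonize(candidates, eroi.scale, config)
    tracks = bin_fragments(fragments, eroi.scale, config)
    return finalize_tracks(tracks, config)
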