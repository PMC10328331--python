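"""Bleb-like feature detection on the cropped dendrite ROI.

Degenerating dendrites develop roughly circular swellings ("blebs",
beads-on-a-string morphology). Because blebs are wider than the dendrite
itself, eroding the binarized image with a horizontal line element longer
than the dendrite width erases the thin vertical dendrites and leaves
pixel clusters only where a feature sits. Those clusters are jagged and
horizontally biased, so each seed is refined with Chan-Vese active-contour
region growing before shape descriptors are measured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, minimum_filter1d
from scipy.spatial import ConvexHull, QhullError
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, white_tophat
from skimage.segmentation import morphological_chan_vese
from skimage.transform import rescale

from .config import AnalysisConfig, PixelScale
from .cropping import DendriteROI, circularity
from .errors import NoDendritesError

__all__ = ["BlebFeature", "EnhancedROI", "enhance", "threshold_dendrites",
           "threshold_value", "erode_seeds", "refine_features",
           "detect_features", "min_max_caliper", "region_descriptors"]


@dataclass
class BlebFeature:
    """One detected morphological abnormality on (or near) a dendrite.

    Positions and sizes are physical (um) in ROI coordinates; intensity is
    in the native units of the original, un-enhanced image so it stays
    comparable across images. ``dendrite_index`` is 0 until the feature is
    matched to a track (then 1..4).
    """

    centroid_um: tuple[float, float]    # (y, x)
    area_um2: float
    perimeter_um: float
    circularity: float
    extent: float
    eccentricity: float
    min_caliper_um: float
    max_caliper_um: float
    mean_intensity: float
    dendrite_index: int = 0


@dataclass
class EnhancedROI:
    """ROI after local contrast, background subtraction, and 4x resize."""

    pixels: np.ndarray          # float in [0, 1], 4x the ROI grid
    scale: PixelScale           # resize_factor folded in
    noise_level: float          # robust background dispersion, [0, 1] units
    source: DendriteROI         # the un-enhanced ROI (for native intensities)


def _robust_noise(img: np.ndarray) -> float:
    """MAD-based dispersion (x1.4826) of the below-Otsu background."""
    if img.max() <= img.min():
        return 0.0
    bg = img[img <= threshold_otsu(img)]
    if bg.size == 0:
        return 0.0
    return float(np.median(np.abs(bg - np.median(bg))) * 1.4826)


def enhance(roi: DendriteROI, config: AnalysisConfig | None = None) -> EnhancedROI:
    """Local contrast + background subtraction + 4x bicubic upsampling.

    The CLAHE clip limit is scaled down on noisy images (aggressive local
    equalization amplifies background grain), the white top-hat with a
    physically sized disk removes soma halo and slow illumination trends,
    and the 4x resize gives the morphological steps enough pixels to work
    with at any camera scale.
    """
    config = config or AnalysisConfig()
    img = roi.as_float()
    raw_noise = _robust_noise(img)
    clip = config.clahe_base_clip / (1.0 + 100.0 * raw_noise)
    enhanced = equalize_adapthist(img, clip_limit=clip)
    radius = max(1, int(round(roi.scale.to_px(config.tophat_radius_um))))
    enhanced = white_tophat(enhanced, footprint=disk(radius, decomposition="sequence"))
    enhanced = rescale(enhanced, config.resize_factor, order=3,
                       preserve_range=True, anti_aliasing=False)
    enhanced = np.clip(enhanced, 0.0, 1.0)
    return EnhancedROI(enhanced, roi.scale.resized(config.resize_factor),
                       _robust_noise(enhanced), roi)


def threshold_value(eroi: EnhancedROI, config: AnalysisConfig | None = None) -> float:
    """Noise-adaptive global threshold: Otsu + k x background dispersion."""
    config = config or AnalysisConfig()
    return float(threshold_otsu(eroi.pixels)
                 + config.noise_threshold_k * eroi.noise_level)


def threshold_dendrites(eroi: EnhancedROI,
                        config: AnalysisConfig | None = None) -> np.ndarray:
    """Rough dendrite+feature outline from the noise-adaptive threshold."""
    if eroi.pixels.max() <= eroi.pixels.min():
        raise NoDendritesError("enhanced ROI carries no signal")
    mask = eroi.pixels > threshold_value(eroi, config)
    if not mask.any():
        raise NoDendritesError("empty foreground after thresholding")
    return mask


def erode_seeds(mask: np.ndarray, scale: PixelScale,
                config: AnalysisConfig | None = None) -> list:
    """Horizontal erosion: survivors mark feature locations.

    The line element's physical length (~2x the nominal dendrite width)
    erases anything no wider than a dendrite; surviving components above
    the minimum area are the feature seeds. Survivors touching the
    proximal (bottom) frame edge are residual cell-body glow at the crop
    line, not dendrite features, and are excluded the same way the
    cropper excludes lateral border objects. An empty list is a valid
    outcome (a healthy dendrite has no features).
    """
    config = config or AnalysisConfig()
    length = max(3, int(round(scale.to_px(config.erosion_length_um))))
    eroded = minimum_filter1d(mask.astype(np.uint8), size=length, axis=1,
                              mode="constant", cval=0) == 1
    min_area_px = config.min_feature_area_um2 / scale.effective**2
    n_rows = mask.shape[0]
    return [p for p in regionprops(label(eroded))
            if p.area >= min_area_px and p.bbox[2] < n_rows]


def min_max_caliper(coords: np.ndarray) -> tuple[float, float]:
    """Exact min/max caliper (Feret) diameters of a pixel region, in px.

    Rotating calipers on the convex hull of the pixel corner points, so a
    single pixel has calipers (1, sqrt(2)) rather than (0, 0).
    """
    corners = np.concatenate([coords + d for d in
                              ([0, 0], [0, 1], [1, 0], [1, 1])]).astype(float)
    try:
        hull = ConvexHull(corners)
        pts = corners[hull.vertices]
    except QhullError:  # collinear degenerate region
        pts = corners
    d = pts[:, None, :] - pts[None, :, :]
    max_cal = float(np.sqrt((d**2).sum(-1)).max())
    # min width: for each hull edge, the farthest point from the edge line
    widths = []
    n = len(pts)
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths.append(np.abs((pts - pts[i]) @ normal).max())
    min_cal = float(min(widths)) if widths else max_cal
    return min_cal, max_cal


def region_descriptors(region_mask: np.ndarray, offset: tuple[int, int],
                       eroi: EnhancedROI) -> BlebFeature:
    """Shape + intensity descriptors of one refined feature region.

    Intensities are bilinearly sampled from the original, un-enhanced ROI
    at the region's (downscaled) pixel positions, in native camera units.
    """
    props = regionprops(region_mask.astype(np.uint8))[0]
    eff = eroi.scale.effective
    factor = eroi.scale.resize_factor // eroi.source.scale.resize_factor
    coords = props.coords + np.array(offset)
    cy, cx = props.centroid
    min_cal, max_cal = min_max_caliper(props.coords)
    src_coords = (coords.T.astype(float)) / factor
    intensities = map_coordinates(eroi.source.pixels.astype(float), src_coords,
                                  order=1, mode="nearest")
    return BlebFeature(
        centroid_um=((cy + offset[0]) * eff, (cx + offset[1]) * eff),
        area_um2=props.area * eff**2,
        perimeter_um=max(props.perimeter, 1.0) * eff,
        circularity=circularity(props.area, max(props.perimeter, 1.0)),
        extent=float(props.extent),
        eccentricity=float(props.eccentricity),
        min_caliper_um=min_cal * eff,
        max_caliper_um=max_cal * eff,
        mean_intensity=float(intensities.mean()),
    )


def refine_features(eroi: EnhancedROI, seeds: list,
                    config: AnalysisConfig | None = None) -> list[BlebFeature]:
    """Grow each erosion seed with Chan-Vese and measure the result.

    Each seed is dilated slightly and evolved for a fixed iteration budget
    on a window padded a few um around it. The Chan-Vese energy happily
    follows the bright dendrite out of the bleb, so the evolved region is
    cut back to dendrite-free evidence: spans no wider than a dendrite are
    removed with the same horizontal erosion used for seeding, the wide
    component containing the seed is kept, and its boundary is restored
    with a bounded dilation inside the evolved region. Regions of nearby
    seeds that still overlap are fused into a single feature; a region
    that collapses drops its seed.
    """
    config = config or AnalysisConfig()
    if not seeds:
        return []
    scale = eroi.scale
    pad = int(round(scale.to_px(config.chanvese_window_pad_um)))
    dil = max(1, int(round(scale.to_px(config.chanvese_seed_dilation_um))))
    erosion_len = max(3, int(round(scale.to_px(config.erosion_length_um))))
    refined = np.zeros(eroi.pixels.shape, dtype=bool)
    H, W = eroi.pixels.shape
    for seed in seeds:
        r0, c0, r1, c1 = seed.bbox
        r0, c0 = max(0, r0 - pad), max(0, c0 - pad)
        r1, c1 = min(H, r1 + pad), min(W, c1 + pad)
        window = eroi.pixels[r0:r1, c0:c1]
        init = np.zeros(window.shape, dtype=bool)
        init[seed.coords[:, 0] - r0, seed.coords[:, 1] - c0] = True
        init = dilation(init, disk(dil))
        evolved = morphological_chan_vese(window, num_iter=config.chanvese_iterations,
                                          init_level_set=init, smoothing=1) > 0
        wide = minimum_filter1d(evolved.astype(np.uint8), size=erosion_len,
                                axis=1, mode="constant", cval=0) == 1
        labels = label(wide)
        hit = np.unique(labels[init & wide])
        hit = hit[hit > 0]
        if hit.size == 0:
            continue  # contour collapsed; seed dropped
        keep = dilation(np.isin(labels, hit), disk(erosion_len // 2)) & evolved
        refined[r0:r1, c0:c1] |= keep

    out = []
    for p in regionprops(label(refined)):
        r0, c0, r1, c1 = p.bbox
        sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        sub[p.coords[:, 0] - r0, p.coords[:, 1] - c0] = True
        out.append(region_descriptors(sub, (r0, c0), eroi))
    return out


def detect_features(eroi: EnhancedROI,
                    config: AnalysisConfig | None = None) -> list[BlebFeature]:
    """Threshold, erode, and refine: the full feature-detection stage."""
    config = config or AnalysisConfig()
    mask = threshold_dendrites(eroi, config)
    seeds = erode_seeds(mask, eroi.scale, config)
    return refine_features(eroi, seeds, config)
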