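"""Locate cell bodies, orient the head, and crop to a dendrites-only ROI.

The four CEP somas are the brightest mass in a well-acquired frame. The
cropper finds them with a brightest-pixel threshold, rotates the frame so
the soma row is horizontal (hence the dendrites vertical), splits the
frame at the soma bounding box, keeps the half with elongated vertical
structures rather than circular ones, and finally removes border clutter
and tightens the crop. The returned ROI is in canonical orientation: the
proximal (cell-body) edge is always the bottom edge, so "distance from
the cell body" increases upward for every downstream metric.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import rotate

from .config import AnalysisConfig, PixelScale
from .errors import BlankFrameError, MultipleWormsError, NoCellBodyError, NoDendritesError
from .io import ProjectionImage

__all__ = ["CellBodyCluster", "DendriteROI", "stretch_contrast",
           "segment_cell_bodies", "orient_image", "split_and_select",
           "finalize_crop", "crop_dendrites", "circularity"]


@dataclass
class CellBodyCluster:
    """The connected bright cluster(s) identified as cell bodies."""

    mask: np.ndarray
    centroids: list[tuple[float, float]]          # (row, col) px
    bounding_box: tuple[int, int, int, int]       # (top, left, height, width)
    axis_angle: float                             # degrees in (-90, 90]


@dataclass
class DendriteROI:
    """Oriented, cropped, dendrites-only image with physical scale.

    ``proximal_edge`` is always ``"bottom"``: the row index increases
    toward the cell bodies. ``transform`` records the rotation angle and
    crop offsets mapping ROI coordinates back to the source frame.
    """

    pixels: np.ndarray
    bit_depth: int
    scale: PixelScale
    proximal_edge: str = "bottom"
    transform: dict = field(default_factory=dict)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64) / self.max_value


def circularity(area: float, perimeter: float) -> float:
    """4*pi*A/P^2, clipped to [0, 1.05] (small discrete disks can exceed 1)."""
    if perimeter <= 0:
        return 0.0
    return float(np.clip(4.0 * np.pi * area / perimeter**2, 0.0, 1.05))


def stretch_contrast(img: ProjectionImage,
                     config: AnalysisConfig | None = None) -> ProjectionImage:
    """Linearly rescale between low/high percentiles to the full bit range.

    Protects the downstream brightest-pixel soma threshold from single hot
    pixels while lifting dim dendrites above the detection floor.
    """
    config = config or AnalysisConfig()
    lo, hi = np.percentile(img.pixels,
                           [config.stretch_low_pct, config.stretch_high_pct])
    if hi <= lo:
        raise BlankFrameError("degenerate contrast window (uniform image)")
    out = (img.pixels.astype(np.float64) - lo) / (hi - lo)
    out = np.clip(out, 0.0, 1.0) * img.max_value
    dtype = np.uint16 if img.bit_depth == 16 else np.uint8
    return ProjectionImage(np.round(out).astype(dtype), img.bit_depth,
                           img.scale, img.source_path)


def segment_cell_bodies(img: ProjectionImage,
                        config: AnalysisConfig | None = None) -> CellBodyCluster:
    """Find the soma cluster by thresholding the brightest pixels.

    Components surviving a minimum-area filter are grouped by
    single-linkage clustering of their centroids; more than one group
    farther apart than the configured distance means more than one worm
    is in the frame, which the pipeline does not support.
    """
    config = config or AnalysisConfig()
    scale = img.scale
    # the contrast stretch saturates the brightest 0.1% of pixels, so the
    # somas sit near full range regardless of framing or noise; a fixed
    # fraction of the range isolates them
    max_val = 2 ** img.bit_depth - 1
    thr = config.soma_threshold_frac * max_val
    mask = img.pixels >= thr
    labels = label(mask)
    min_area_px = config.min_soma_area_um2 / scale.effective**2
    # compactness guard: in a somas-missing frame the contrast stretch
    # saturates the dendrites instead, but those are far more elongated
    # than any cell body (even a merged soma row)
    props = [p for p in regionprops(labels)
             if p.area >= min_area_px
             and p.axis_major_length <= config.soma_max_elongation
             * max(p.axis_minor_length, 1.0)]
    if not props:
        raise NoCellBodyError("no cell body found above the soma threshold")

    centroids = np.array([p.centroid for p in props])
    if len(props) > 1:
        cut_px = scale.to_px(config.multiworm_linkage_um)
        groups = fcluster(linkage(centroids, method="single"), cut_px,
                          criterion="distance")
        if groups.max() > 1:
            raise MultipleWormsError(
                f"{groups.max()} separated cell-body groups: multiple worms in frame"
            )

    keep = np.isin(labels, [p.label for p in props])
    rows, cols = np.nonzero(keep)
    bbox = (int(rows.min()), int(cols.min()),
            int(rows.max() - rows.min() + 1), int(cols.max() - cols.min() + 1))

    if len(props) >= 3:
        # line fit through centroids; angle of that line from horizontal
        dc = centroids[:, 1] - centroids[:, 1].mean()
        dr = centroids[:, 0] - centroids[:, 0].mean()
        angle = np.rad2deg(np.arctan2((dc * dr).sum(), (dc * dc).sum())) \
            if np.ptp(centroids[:, 1]) > 1e-9 else 90.0
    else:
        # fall back to the merged cluster's principal axis
        o = regionprops(keep.astype(np.uint8))[0].orientation
        # orientation is the major axis vs the row axis; convert to
        # "angle of the soma line from horizontal"
        angle = 90.0 - abs(np.rad2deg(o))
        angle *= -np.sign(np.rad2deg(o)) if o != 0 else 1.0
    angle = ((angle + 90.0) % 180.0) - 90.0  # report modulo 180 in (-90, 90]
    return CellBodyCluster(keep, [tuple(c) for c in centroids], bbox, float(angle))


def orient_image(img: ProjectionImage, cluster: CellBodyCluster,
                 config: AnalysisConfig | None = None
                 ) -> tuple[ProjectionImage, CellBodyCluster, float]:
    """Rotate so the soma line is horizontal (dendrites vertical).

    The 180-degree ambiguity (somas above vs below the dendrites) is not
    resolved here; side selection handles it. Returns the rotated image,
    the re-segmented cluster, and the applied angle in degrees.
    """
    config = config or AnalysisConfig()
    angle = cluster.axis_angle
    if abs(angle) < 0.25:
        return img, cluster, 0.0
    rot = rotate(img.pixels.astype(np.float64), -angle, resize=True, order=1,
                 mode="constant", cval=float(np.median(img.pixels)),
                 preserve_range=True)
    dtype = np.uint16 if img.bit_depth == 16 else np.uint8
    out = ProjectionImage(np.round(np.clip(rot, 0, img.max_value)).astype(dtype),
                          img.bit_depth, img.scale, img.source_path)
    new_cluster = segment_cell_bodies(out, config)
    return out, new_cluster, -angle


def _side_score(half: np.ndarray, scale: PixelScale,
                config: AnalysisConfig) -> tuple[int, float]:
    """(count of elongated vertical components, summed major-axis length)."""
    if half.size == 0 or half.max() == half.min():
        return 0, 0.0
    mask = half > threshold_otsu(half)
    props = regionprops(label(mask))
    count, total = 0, 0.0
    min_major = scale.to_px(config.min_dendrite_major_axis_um)
    for p in props:
        if p.axis_major_length < min_major:
            continue
        if abs(np.rad2deg(p.orientation)) > config.max_dendrite_orientation_deg:
            continue
        if circularity(p.area, p.perimeter) > config.max_dendrite_circularity:
            continue
        count += 1
        total += p.axis_major_length
    return count, float(total)


def split_and_select(img: ProjectionImage, cluster: CellBodyCluster,
                     config: AnalysisConfig | None = None) -> DendriteROI:
    """Split at the soma bounding box and keep the dendrite-bearing half.

    Each half is binarized with a permissive (Otsu) threshold and scored
    by its count of elongated, near-vertical, non-circular components;
    the half with more such evidence wins. The winner is flipped if
    needed so the proximal (soma) edge ends up at the bottom.
    """
    config = config or AnalysisConfig()
    top, _, height, _ = cluster.bounding_box
    pad = int(round(img.scale.to_px(config.split_pad_um)))  # clears soma halo
    upper = img.pixels[:max(0, top - pad)]
    lower = img.pixels[top + height + pad:]

    up_score = _side_score(upper, img.scale, config)
    lo_score = _side_score(lower, img.scale, config)
    if up_score == (0, 0.0) and lo_score == (0, 0.0):
        raise NoDendritesError("no elongated vertical component on either side")

    if up_score > lo_score:
        pixels, flipped, row_offset = upper, False, 0
    else:
        pixels, flipped, row_offset = np.flipud(lower), True, top + height + pad
    return DendriteROI(
        pixels.copy(), img.bit_depth, img.scale,
        transform={"flipped": flipped, "row_offset": row_offset,
                   "col_offset": 0, "side": "upper" if not flipped else "lower"},
    )


def finalize_crop(roi: DendriteROI,
                  config: AnalysisConfig | None = None) -> DendriteROI:
    """Remove border clutter and residual soma fragments, then crop tight.

    Components touching the lateral borders are dropped, as is any
    component that is both as circular and as large as a soma. The
    remaining mask is cropped to its bounding box plus a physical margin.
    """
    config = config or AnalysisConfig()
    scale = roi.scale
    px = roi.pixels
    if px.max() == px.min():
        raise NoDendritesError("empty ROI after side selection")
    mask = px > threshold_otsu(px)
    labels = label(mask)
    keep = np.zeros_like(mask)
    min_major = scale.to_px(config.min_dendrite_major_axis_um)
    area_cut = config.soma_area_cutoff_um2 / scale.effective**2
    any_elongated = False
    for p in regionprops(labels):
        _, left, _, right = p.bbox
        if left == 0 or right == px.shape[1]:
            continue  # lateral border clutter
        if (circularity(p.area, p.perimeter) > config.soma_circularity_cutoff
                and p.area > area_cut):
            continue  # soma-like fragment
        keep[labels == p.label] = True
        if p.axis_major_length >= min_major:
            any_elongated = True
    if not any_elongated:
        raise NoDendritesError("cleanup removed every elongated component")

    cleaned = np.where(keep | ~mask, px, 0)  # zero removed objects only
    rows, cols = np.nonzero(keep)
    margin = int(round(scale.to_px(config.crop_margin_um)))
    r0 = max(0, rows.min() - margin)
    r1 = min(px.shape[0], rows.max() + 1 + margin)
    c0 = max(0, cols.min() - margin)
    c1 = min(px.shape[1], cols.max() + 1 + margin)
    if r1 - r0 < config.min_roi_height_px:
        raise NoDendritesError("ROI too short after cropping")
    tr = dict(roi.transform)
    tr["crop"] = (int(r0), int(c0))
    return DendriteROI(cleaned[r0:r1, c0:c1], roi.bit_depth, scale, transform=tr)


def crop_dendrites(img: ProjectionImage,
                   config: AnalysisConfig | None = None
                   ) -> tuple[DendriteROI, float]:
    """Full cropping stage: stretch, segment, orient, split, finalize.

    Returns the canonical ROI and the rotation angle that was applied.
    """
    config = config or AnalysisConfig()
    stretched = stretch_contrast(img, config)
    cluster = segment_cell_bodies(stretched, config)
    oriented, cluster, angle = orient_image(stretched, cluster, config)
    roi = split_and_select(oriented, cluster, config)
    roi = finalize_crop(roi, config)
    roi.transform["rotation_deg"] = angle
    return roi, angle
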