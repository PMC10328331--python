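"""Pipeline orchestration: crop -> features -> tracks -> metrics per image."""
from __future__ import annotations

import logging
from pathlib import Path

from .config import AnalysisConfig, PixelScale
from .cropping import crop_dendrites
from .errors import PipelineError
from .features import detect_features, enhance
from .io import ProjectionImage, load_image
from .metrics import (DendriteReport, binarize_for_breaks, compute_report,
                      detect_breaks, match_features)
from .tracking import track_dendrites

__all__ = ["analyze_projection", "run_pipeline"]

log = logging.getLogger("cepquant")


def analyze_projection(img: ProjectionImage,
                       config: AnalysisConfig | None = None,
                       image_id: str = "",
                       return_intermediates: bool = False):
    """Run the full analysis on one in-memory projection image.

    Returns the per-dendrite reports; with ``return_intermediates`` also a
    dict of the ROI, enhanced image, features, tracks, and break segments
    (useful for overlays, sidecars, and debugging).
    """
    config = config or AnalysisConfig()
    image_id = image_id or img.source_path
    roi, _ = crop_dendrites(img, config)
    eroi = enhance(roi, config)
    features = detect_features(eroi, config)
    tracks = track_dendrites(eroi, config)
    break_mask = binarize_for_breaks(eroi, config)
    features = match_features(features, tracks, config)
    reports: list[DendriteReport] = []
    breaks_all = []
    for tr in tracks:
        breaks = detect_breaks(tr, break_mask, config)
        breaks_all.extend(breaks)
        reports.append(compute_report(roi, tr, breaks, features,
                                      image=image_id, config=config))
    if return_intermediates:
        return reports, {"roi": roi, "eroi": eroi, "features": features,
                         "tracks": tracks, "breaks": breaks_all}
    return reports


def run_pipeline(paths: list[str | Path], scale: PixelScale,
                 config: AnalysisConfig | None = None
                 ) -> tuple[list[DendriteReport], dict[str, str]]:
    """Analyze a batch of image files, skipping (and logging) failures.

    Returns the pooled reports and a per-image status map ("ok" or the
    failure reason). Raises only when the path list is empty or every
    single image fails.
    """
    if not paths:
        raise ValueError("no input images given")
    config = config or AnalysisConfig()
    reports: list[DendriteReport] = []
    status: dict[str, str] = {}
    for path in paths:
        name = str(path)
        try:
            img = load_image(path, scale)
            rs = analyze_projection(img, config, image_id=name)
            reports.extend(rs)
            status[name] = "ok"
            log.info("%s: %d dendrites", name, len(rs))
        except PipelineError as exc:
            status[name] = f"{type(exc).__name__}: {exc}"
            log.warning("skipping %s: %s", name, exc)
    if all(v != "ok" for v in status.values()):
        raise PipelineError(
            "all images failed: " + "; ".join(f"{k} -> {v}" for k, v in status.items())
        )
    return reports, status
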