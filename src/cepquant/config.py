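"""Physical scaling and tunable parameters.

All size-dependent parameters are expressed in microns and converted to
pixels at their use sites through :class:`PixelScale`. This is what makes
one parameter set portable across microscope setups: the same analysis
runs on a 63x/0.1 um-per-px camera and a 40x/0.2 um-per-px camera by
changing only the pixel size.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PixelScale:
    """Physical scale of an image.

    Parameters
    ----------
    microns_per_pixel : float
        Camera pixel size in um/px (must be positive).
    resize_factor : int
        Integer upsampling factor applied to the grid (default 1). The
        effective scale is ``microns_per_pixel / resize_factor``.
    """

    microns_per_pixel: float
    resize_factor: int = 1

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.resize_factor < 1 or int(self.resize_factor) != self.resize_factor:
            raise ValueError("resize_factor must be a positive integer")

    @property
    def effective(self) -> float:
        """Effective um/px of the (possibly resized) grid."""
        return self.microns_per_pixel / self.resize_factor

    def to_px(self, microns: float) -> float:
        """Convert a physical length in um to (effective) pixels."""
        return microns / self.effective

    def to_um(self, pixels: float) -> float:
        """Convert a pixel count on this grid to um."""
        return pixels * self.effective

    def resized(self, factor: int) -> "PixelScale":
        """Scale for a grid upsampled by ``factor`` relative to this one."""
        return PixelScale(self.microns_per_pixel, self.resize_factor * factor)


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with documented defaults.

    Lengths and areas are physical (um, um^2); they are converted to pixels
    via the image's :class:`PixelScale` where used, never stored as raw
    pixel counts.
    """

    # --- ROI cropping ---
    stretch_low_pct: float = 0.5        # global contrast stretch percentiles
    stretch_high_pct: float = 99.9
    soma_threshold_frac: float = 0.7    # of full range, after contrast stretch
    min_soma_area_um2: float = 4.0
    soma_max_elongation: float = 10.0   # axis ratio; somas are compact
    multiworm_linkage_um: float = 25.0  # single-linkage cut for worm grouping
    min_dendrite_major_axis_um: float = 10.0
    max_dendrite_orientation_deg: float = 30.0  # from vertical
    max_dendrite_circularity: float = 0.5
    soma_circularity_cutoff: float = 0.7
    soma_area_cutoff_um2: float = 8.0
    crop_margin_um: float = 2.0
    split_pad_um: float = 0.5           # extra clearance from the soma bbox
    min_roi_height_px: int = 32

    # --- feature detection ---
    resize_factor: int = 4
    clahe_base_clip: float = 0.01       # CLAHE clip limit at zero noise
    tophat_radius_um: float = 2.0
    noise_threshold_k: float = 1.0      # threshold = Otsu + k * noise_level
    erosion_length_um: float = 1.4      # ~2x nominal dendrite width
    min_feature_area_um2: float = 0.25
    chanvese_iterations: int = 60
    chanvese_seed_dilation_um: float = 0.3
    chanvese_window_pad_um: float = 3.0

    # --- dendrite tracking ---
    peak_prominence_noise_mult: float = 2.0
    peak_prominence_floor: float = 0.02  # fraction of range, noiseless safety net
    min_peak_separation_um: float = 1.0
    vertical_closing_um: float = 5.0
    ema_weight: float = 0.1             # running-average update per row
    gating_distance_um: float = 2.0
    seeding_row_fraction: float = 0.25  # new tracks only in distal region
    smoothing_window_um: float = 2.0
    min_track_evidence_um: float = 5.0  # summed detected rows to keep a track
    track_end_min_run_um: float = 1.0   # contiguous support required at ends

    # --- break detection & metrics ---
    break_threshold_fraction: float = 0.5  # x feature-detection threshold
    lateral_probe_um: float = 0.5
    min_break_length_um: float = 0.5
    feature_gate_um: float = 5.0        # feature-to-track matching gate
    min_reliable_length_um: float = 5.0

    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key = value`` text file, ignoring blanks and '#'."""
        values: dict[str, object] = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            values[key] = int(raw) if fields[key] == "int" else float(raw)
        return cls(**values)  # type: ignore[arg-type]
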