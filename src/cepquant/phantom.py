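"""Ground-truth-annotated synthetic images of the *C. elegans* head.

A phantom emulates a maximum-projection fluorescence image of the four
cephalic (CEP) dopaminergic neurons: four bright cell bodies in a row at
the proximal end, four roughly parallel, slightly curved dendrites
(Gaussian cross-section, ~0.5-1 um wide) running away from them, with
optional bleb-like Gaussian swellings, zeroed break spans, a linear
background ramp, Gaussian read noise, Poisson shot noise, arbitrary frame
rotation, and 8- or 16-bit quantization. Every stochastic element is
driven by the spec's seed, so the same spec always renders the identical
image, and each render is accompanied by the ground truth the pipeline
should recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import SimilarityTransform, warp

from .config import PixelScale
from .errors import PhantomSpecError
from .io import ProjectionImage

__all__ = ["PhantomSpec", "PhantomTruth", "BlebRecord", "BreakRecord",
           "render", "fixture_suite"]

# intensity plateaus as fractions of the dynamic range
_BACKGROUND = 0.03
_DENDRITE_PEAK = 0.35
_SOMA_PEAK = 0.90
_BLEB_GAIN = 1.5  # bleb peak relative to the dendrite peak


@dataclass(frozen=True)
class BlebRecord:
    """One synthetic bleb: which dendrite, where along it, how big."""

    dendrite_index: int               # 1..n_dendrites
    position: float                   # normalized arc position, 0=proximal
    diameter_um: float                # FWHM of the Gaussian blob
    peak_fraction: float | None = None  # of dynamic range; None -> 1.5x dendrite


@dataclass(frozen=True)
class BreakRecord:
    """One synthetic break: a zeroed span of a dendrite."""

    dendrite_index: int
    start: float                      # normalized arc position of span start
    length_um: float


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head image."""

    pixel_size: float = 0.1           # um/px
    bit_depth: int = 16
    image_size: tuple[int, int] = (560, 320)  # (rows, cols)
    n_dendrites: int = 4
    dendrite_length_um: float = 40.0
    dendrite_width_um: float = 0.8    # FWHM of the ridge cross-section
    dendrite_spacing_um: float = 5.0
    curvature_amplitude_um: float = 1.0
    rotation_deg: float = 0.0
    soma_diameter_um: float = 4.0     # 0 disables somas
    blebs: Sequence[BlebRecord] = field(default_factory=tuple)
    breaks: Sequence[BreakRecord] = field(default_factory=tuple)
    noise_sigma: float = 0.0          # Gaussian read noise, fraction of range
    photon_budget: float = 0.0        # Poisson shot noise; 0 disables
    background_gradient: float = 0.0  # ramp amplitude across rows
    second_worm_offset_um: float | None = None  # renders a second head
    seed: int = 0

    def validate(self) -> None:
        if self.n_dendrites not in range(0, 5):
            raise PhantomSpecError("n_dendrites must be 0..4")
        if self.bit_depth not in (8, 16):
            raise PhantomSpecError("bit_depth must be 8 or 16")
        for b in self.blebs:
            if not 1 <= b.dendrite_index <= self.n_dendrites:
                raise PhantomSpecError(f"bleb references dendrite {b.dendrite_index}")
            if not 0.0 <= b.position <= 1.0:
                raise PhantomSpecError("bleb position must be in [0, 1]")
        for br in self.breaks:
            if not 1 <= br.dendrite_index <= self.n_dendrites:
                raise PhantomSpecError(f"break references dendrite {br.dendrite_index}")
            frac = br.length_um / self.dendrite_length_um
            if br.start < 0 or br.start + frac > 1.0:
                raise PhantomSpecError("break span must lie within [0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth for one rendered phantom, in post-rotation coordinates."""

    centerlines_um: list[np.ndarray]        # per dendrite, (N, 2) of (y, x) um
    lengths_um: list[float]
    percent_remaining: list[float]
    break_lengths_um: list[list[float]]
    bleb_counts: list[int]
    blebs: list[list[BlebRecord]]
    bleb_positions_um: list[list[tuple[float, float]]]  # (y, x) per bleb
    expected_scores: list[int]
    rotation_deg: float
    soma_centers_um: list[tuple[float, float]] = field(default_factory=list)


def _rotation_tform(shape: tuple[int, int], angle_deg: float):
    """Replicate skimage.transform.rotate(resize=True) geometry.

    Returns (output->input transform for warping, output shape). The
    forward (input->output) point map is the transform's ``inverse``.
    """
    rows, cols = shape
    center = np.array((cols, rows)) / 2.0 - 0.5
    t1 = SimilarityTransform(translation=center)
    t2 = SimilarityTransform(rotation=np.deg2rad(angle_deg))
    t3 = SimilarityTransform(translation=-center)
    tform = t3 + t2 + t1
    corners = np.array([[0, 0], [0, rows - 1], [cols - 1, 0], [cols - 1, rows - 1]])
    corners = tform.inverse(corners)
    minc, minr = corners[:, 0].min(), corners[:, 1].min()
    maxc, maxr = corners[:, 0].max(), corners[:, 1].max()
    out_shape = (int(np.ceil(maxr - minr + 1)), int(np.ceil(maxc - minc + 1)))
    t4 = SimilarityTransform(translation=(minc, minr))
    return t4 + tform, out_shape


def _centerline_px(spec: PhantomSpec, idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Pre-rotation centerline of dendrite ``idx`` (0-based).

    Returns (rows, cols) float arrays ordered proximal -> distal, one sample
    per pixel row.
    """
    px = spec.pixel_size
    rows, cols = spec.image_size
    spacing = spec.dendrite_spacing_um / px
    x0 = (cols - 1) / 2 + (idx - (spec.n_dendrites - 1) / 2) * spacing
    soma_r = spec.soma_diameter_um / 2 / px
    y_base = rows - 1 - soma_r - 4  # just above the soma row
    length_px = spec.dendrite_length_um / px
    n = int(round(length_px)) + 1
    s = np.linspace(0.0, 1.0, n)
    ys = y_base - s * length_px
    # gentle bow, alternating direction so dendrites stay separated
    bow = spec.curvature_amplitude_um / px
    xs = x0 + bow * np.sin(np.pi * s) * (1 if idx % 2 == 0 else -1)
    return ys, xs


def _render_worm(canvas: np.ndarray, spec: PhantomSpec, col_offset: float) -> None:
    """Draw somas + dendrites (+blebs, -breaks) onto ``canvas`` in place."""
    px = spec.pixel_size
    rows, cols = canvas.shape
    sigma = spec.dendrite_width_um / 2.355 / px
    col_grid = np.arange(cols, dtype=np.float64)

    for idx in range(spec.n_dendrites):
        ys, xs = _centerline_px(spec, idx)
        xs = xs + col_offset
        amp = np.full(ys.shape, _DENDRITE_PEAK)
        for br in spec.breaks:
            if br.dendrite_index == idx + 1:
                frac = br.length_um / spec.dendrite_length_um
                s = np.linspace(0, 1, len(ys))
                amp[(s >= br.start) & (s <= br.start + frac)] = 0.0
        for yi, xi, a in zip(ys, xs, amp):
            r = int(round(yi))
            if 0 <= r < rows and a > 0:
                profile = a * np.exp(-((col_grid - xi) ** 2) / (2 * sigma**2))
                np.maximum(canvas[r], profile, out=canvas[r])

    for b in spec.blebs:
        ys, xs = _centerline_px(spec, b.dendrite_index - 1)
        i = int(round(b.position * (len(ys) - 1)))
        cy, cx = ys[i], xs[i] + col_offset
        peak = b.peak_fraction if b.peak_fraction is not None else _BLEB_GAIN * _DENDRITE_PEAK
        bs = b.diameter_um / 2.355 / px
        half = int(np.ceil(4 * bs))
        r0, r1 = max(0, int(cy) - half), min(rows, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(cols, int(cx) + half + 1)
        if r0 >= r1 or c0 >= c1:
            raise PhantomSpecError("bleb outside the frame")
        yy, xx = np.mgrid[r0:r1, c0:c1]
        blob = peak * np.exp(-(((yy - cy) ** 2) + (xx - cx) ** 2) / (2 * bs**2))
        np.maximum(canvas[r0:r1, c0:c1], blob, out=canvas[r0:r1, c0:c1])

    if spec.soma_diameter_um > 0:
        soma_r = spec.soma_diameter_um / 2 / px
        y_soma = rows - 1 - soma_r - 2
        ss = soma_r / 1.5  # soft-edged disk
        for idx in range(spec.n_dendrites if spec.n_dendrites else 4):
            _, xs = _centerline_px(spec, idx)
            cx = xs[0] + col_offset
            half = int(np.ceil(3 * soma_r))
            r0, r1 = max(0, int(y_soma) - half), min(rows, int(y_soma) + half + 1)
            c0, c1 = max(0, int(cx) - half), min(cols, int(cx) + half + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            d2 = (yy - y_soma) ** 2 + (xx - cx) ** 2
            disk = np.where(
                d2 <= soma_r**2, _SOMA_PEAK,
                _SOMA_PEAK * np.exp(-(np.sqrt(d2) - soma_r) ** 2 / (2 * ss**2)),
            )
            np.maximum(canvas[r0:r1, c0:c1], disk, out=canvas[r0:r1, c0:c1])


def render(spec: PhantomSpec) -> tuple[ProjectionImage, PhantomTruth]:
    """Render a phantom and its ground-truth annotation.

    The clean scene is composed in an upright frame (somas at the bottom,
    dendrites running up), degraded with the background ramp and noise,
    rotated last, and quantized to the requested bit depth. Truth
    centerlines and bleb positions are reported in post-rotation pixel
    coordinates converted to um.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    rows, cols = spec.image_size

    canvas = np.full((rows, cols), _BACKGROUND, dtype=np.float64)
    if spec.second_worm_offset_um is not None:
        half = spec.second_worm_offset_um / px / 2  # heads straddle the center
        _render_worm(canvas, spec, col_offset=-half)
        _render_worm(canvas, spec, col_offset=half)
    else:
        _render_worm(canvas, spec, col_offset=0.0)

    if spec.background_gradient:
        ramp = np.linspace(0, spec.background_gradient, rows)[:, None]
        canvas = canvas + ramp
    if spec.photon_budget > 0:
        canvas = rng.poisson(np.clip(canvas, 0, None) * spec.photon_budget) / spec.photon_budget
    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)

    if spec.rotation_deg % 360 != 0:
        tform, out_shape = _rotation_tform((rows, cols), spec.rotation_deg)
        canvas = warp(canvas, tform, output_shape=out_shape, order=1,
                      mode="constant", cval=_BACKGROUND, preserve_range=True)
        fwd = tform.inverse  # input (x, y) -> output (x, y)
    else:
        fwd = None

    canvas = np.clip(canvas, 0.0, 1.0)
    max_val = 2 ** spec.bit_depth - 1
    pixels = np.round(canvas * max_val).astype(np.uint16 if spec.bit_depth == 16 else np.uint8)
    img = ProjectionImage(pixels, spec.bit_depth, PixelScale(px), source_path="<phantom>")

    def map_point(r: float, c: float) -> tuple[float, float]:
        if fwd is None:
            return r, c
        x, y = fwd(np.array([[c, r]]))[0]
        return float(y), float(x)

    centerlines, lengths, pct_rem, brk_lengths = [], [], [], []
    bleb_counts, bleb_lists, bleb_pos, scores = [], [], [], []
    from .metrics import score_from_values

    for idx in range(spec.n_dendrites):
        ys, xs = _centerline_px(spec, idx)
        pts = np.array([map_point(r, c) for r, c in zip(ys, xs)])
        out_rows, out_cols = pixels.shape
        if (pts[:, 0].min() < -1 or pts[:, 0].max() > out_rows
                or pts[:, 1].min() < -1 or pts[:, 1].max() > out_cols):
            raise PhantomSpecError("dendrite leaves the frame after rotation")
        centerlines.append(pts * px)
        lengths.append(spec.dendrite_length_um)
        brs = [b.length_um for b in spec.breaks if b.dendrite_index == idx + 1]
        brk_lengths.append(brs)
        pct = 100.0 * (spec.dendrite_length_um - sum(brs)) / spec.dendrite_length_um
        pct_rem.append(pct)
        dblebs = [b for b in spec.blebs if b.dendrite_index == idx + 1]
        bleb_counts.append(len(dblebs))
        bleb_lists.append(dblebs)
        positions = []
        for b in dblebs:
            i = int(round(b.position * (len(ys) - 1)))
            r, c = map_point(ys[i], xs[i])
            positions.append((r * px, c * px))
        bleb_pos.append(positions)
        scores.append(score_from_values(pct, len(dblebs)))

    soma_centers = []
    if spec.soma_diameter_um > 0:
        soma_r = spec.soma_diameter_um / 2 / px
        y_soma = rows - 1 - soma_r - 2
        for idx in range(spec.n_dendrites if spec.n_dendrites else 4):
            _, xs = _centerline_px(spec, idx)
            r, c = map_point(y_soma, xs[0])
            soma_centers.append((r * px, c * px))

    truth = PhantomTruth(centerlines, lengths, pct_rem, brk_lengths,
                         bleb_counts, bleb_lists, bleb_pos, scores,
                         spec.rotation_deg, soma_centers)
    return img, truth


def fixture_suite() -> list[tuple[str, PhantomSpec]]:
    """A fixed catalogue of phantoms exercising every pipeline regime.

    Covers: a healthy head, one spec per categorical score bin 0-4, a
    multi-worm frame, a somas-missing frame, +/-30 degree rotations, both
    bit depths, and the two camera scales (0.1 and 0.2 um/px).
    """
    blebs3 = tuple(BlebRecord(2, p, 2.5) for p in (0.25, 0.5, 0.75))
    blebs6 = tuple(BlebRecord(3, p, 2.5) for p in (0.15, 0.3, 0.45, 0.6, 0.75, 0.9))
    break30 = (BreakRecord(1, 0.35, 12.0),)                 # 70% remaining
    break60 = (BreakRecord(4, 0.10, 10.0), BreakRecord(4, 0.55, 15.0))  # 37.5%

    suite = [
        ("healthy", PhantomSpec(seed=7)),
        ("score0_noisy", PhantomSpec(noise_sigma=0.02, photon_budget=500, seed=11)),
        ("score1_blebs3", PhantomSpec(blebs=blebs3, noise_sigma=0.02, seed=12)),
        ("score2_blebs6", PhantomSpec(blebs=blebs6, noise_sigma=0.02, seed=13)),
        ("score3_break", PhantomSpec(breaks=break30, noise_sigma=0.02, seed=14)),
        ("score4_breaks", PhantomSpec(breaks=break60, noise_sigma=0.02, seed=15)),
        ("rotated_plus30", PhantomSpec(rotation_deg=30.0, image_size=(620, 420), seed=16)),
        ("rotated_minus30", PhantomSpec(rotation_deg=-30.0, image_size=(620, 420), seed=17)),
        ("eight_bit", PhantomSpec(bit_depth=8, seed=18)),
        ("coarse_pixels", PhantomSpec(pixel_size=0.2, image_size=(280, 160), seed=19)),
        ("multi_worm", PhantomSpec(image_size=(560, 960), second_worm_offset_um=60.0, seed=20)),
        ("no_somas", PhantomSpec(soma_diameter_um=0.0, seed=21)),
    ]
    return suite
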