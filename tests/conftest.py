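import numpy as np
import pytest

from cepquant import AnalysisConfig, PhantomSpec, PixelScale, analyze_projection, render
from cepquant.cropping import DendriteROI


@pytest.fixture(scope="session")
def healthy_phantom():
    """A clean four-dendrite head phantom and its ground truth."""
    return render(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def healthy_analysis(healthy_phantom):
    """Full pipeline output on the healthy phantom (computed once)."""
    img, truth = healthy_phantom
    reports, inter = analyze_projection(img, return_intermediates=True)
    return reports, inter, truth


@pytest.fixture
def config():
    return AnalysisConfig()


def make_roi(pixels01: np.ndarray, microns_per_pixel: float = 0.1,
             bit_depth: int = 16) -> DendriteROI:
    """Wrap a [0, 1] float array as a canonical ROI (test helper)."""
    max_val = 2 ** bit_depth - 1
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    px = np.round(np.clip(pixels01, 0, 1) * max_val).astype(dtype)
    return DendriteROI(px, bit_depth, PixelScale(microns_per_pixel))


def gaussian_ridge(shape, centers, sigma_px, amplitude=0.35, background=0.03):
    """Vertical Gaussian ridges at the given column centers ([0,1] image)."""
    rows, cols = shape
    img = np.full(shape, background)
    x = np.arange(cols)
    for c in centers:
        img = np.maximum(img, amplitude * np.exp(-((x - c) ** 2) / (2 * sigma_px**2)))
    return img
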