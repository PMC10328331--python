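"""Image loading, maximum projection, and report serialization."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import PixelScale
from .errors import BlankFrameError, ChannelError, InputError

__all__ = [
    "ProjectionImage",
    "load_image",
    "max_project",
    "write_report",
    "read_report",
]


@dataclass
class ProjectionImage:
    """A 2-D maximum-intensity projection with physical scale.

    ``pixels`` is an unsigned-integer grid whose values lie within
    ``[0, 2**bit_depth - 1]``; the frame is at least 64x64 px.
    """

    pixels: np.ndarray
    bit_depth: int
    scale: PixelScale
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if min(self.pixels.shape) < 64:
            raise ValueError("image must be at least 64x64 pixels")

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def as_float(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] floats."""
        return self.pixels.astype(np.float64) / self.max_value


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (page) axis of a stack."""
    if stack.ndim == 2:
        return stack
    return stack.max(axis=0)


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise InputError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")


def load_image(path: str | Path, scale: PixelScale) -> ProjectionImage:
    """Load an 8/16-bit grayscale TIFF or PNG, max-projecting multi-page input.

    Raises
    ------
    InputError
        If the file is missing or not decodable as grayscale uint8/uint16.
    ChannelError
        For RGB(A) input: the fluorescence channel must be extracted upstream
        because channel choice is a scientific decision.
    BlankFrameError
        If the projected frame has zero variance (no signal).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # decoding failure
        raise InputError(f"cannot decode {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ChannelError(
            f"{path} is RGB(A); supply a single-channel image (extract the "
            "GFP channel before analysis)"
        )
    if arr.ndim == 3:
        arr = max_project(arr)
    elif arr.ndim != 2:
        raise InputError(f"{path}: expected a 2-D image or a page stack")

    bit_depth = _infer_bit_depth(arr)
    if arr.max() == arr.min():
        raise BlankFrameError(f"{path}: blank frame (zero intensity variance)")
    return ProjectionImage(arr, bit_depth, scale, source_path=str(path))


def write_report(reports: list, path: str | Path) -> None:
    """Write per-dendrite reports as an RFC-4180 CSV with a header row.

    Columns are the identifiers (image, dendrite index), the fixed 20-metric
    schema in canonical order, and the categorical score last.
    """
    from .metrics import reports_to_frame

    if not reports:
        raise ValueError("no reports to write")
    frame = reports_to_frame(reports)
    frame.to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report written by :func:`write_report` (lossless round trip)."""
    from .metrics import METRIC_COLUMNS

    frame = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"report at {path} is missing metric columns: {missing}")
    return frame
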