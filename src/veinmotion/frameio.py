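"""Grayscale frame sequences and physical-scale metadata.

Conventions used throughout the package:

* intensities are stored as floating point on a 0-255 scale regardless of the
  source bit depth (correlation is intensity-scale invariant, but one fixed
  convention keeps fixtures exact);
* ``x`` is the column index and ``y`` the row index, both 0-based, with the
  origin at the top-left pixel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DimensionMismatchError, DomainError, InputError

__all__ = [
    "GrayFrame",
    "FrameSequence",
    "PixelScale",
    "load_sequence",
    "save_sequence",
    "to_grayscale",
    "pixel_scale",
]

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass
class GrayFrame:
    """A single 2-D grayscale image.

    Parameters
    ----------
    pixels
        2-D float array of intensities on a nominal 0-255 scale.
    index
        Frame ordinal within its sequence (0-based).
    """

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError(f"frame must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InputError("frame must have at least one row and one column")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("frame contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FrameSequence:
    """An ordered, constant-size grayscale frame sequence.

    The base frame (index ``base_index``, default the first frame) is the
    reference against which all displacement fields are computed.
    """

    frames: list[GrayFrame] = field(default_factory=list)
    fps: float = 30.0
    base_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise InputError("sequence contains no frames")
        if self.fps <= 0:
            raise DomainError("fps must be positive")
        shape = self.frames[0].pixels.shape
        for f in self.frames:
            if f.pixels.shape != shape:
                raise DimensionMismatchError(
                    f"frame {f.index} has shape {f.pixels.shape}, expected {shape}"
                )
        if not 0 <= self.base_index < len(self.frames):
            raise InputError("base_index outside the sequence")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> GrayFrame:
        return self.frames[i]

    @property
    def base(self) -> GrayFrame:
        return self.frames[self.base_index]

    @property
    def height(self) -> int:
        return self.frames[0].height

    @property
    def width(self) -> int:
        return self.frames[0].width

    @property
    def duration(self) -> float:
        """Sequence duration in seconds, derived from the frame count."""
        return len(self.frames) / self.fps


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Convert an image array to single-channel float64 on the 0-255 scale.

    RGB(A) images are reduced with fixed BT.601 luma weights; an alpha channel
    is ignored.  Integer inputs are rescaled so their full dtype range maps to
    0-255 (uint8 passes through unchanged); float inputs are taken verbatim.
    Already-gray input is returned unchanged, so the conversion is idempotent.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = np.tensordot(arr[:, :, :3].astype(np.float64), LUMA_WEIGHTS, axes=([2], [0]))
    elif arr.ndim != 2:
        raise InputError(f"cannot interpret array of shape {arr.shape} as an image")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scale = 255.0 / info.max if info.max != 255 else 1.0
        arr = arr.astype(np.float64) * scale
    else:
        arr = arr.astype(np.float64)
    return arr


def _list_image_files(directory: Path) -> list[Path]:
    files = [
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    ]
    return sorted(files, key=lambda p: p.name)


def load_sequence(path: str | os.PathLike, fps: float = 30.0, base_index: int = 0) -> FrameSequence:
    """Load an image-file directory (or a video file) as a grayscale sequence.

    A directory is the canonical input: lexicographic file order defines frame
    order.  Video files are decoded with imageio if a suitable backend is
    available.

    Raises
    ------
    InputError
        Empty directory, unreadable file, or missing video backend.
    DimensionMismatchError
        Frames of differing dimensions.
    """
    path = Path(path)
    if path.is_dir():
        files = _list_image_files(path)
        if not files:
            raise InputError(f"no image files found in {path}")
        frames = []
        for i, f in enumerate(files):
            try:
                arr = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - surface as our input error
                raise InputError(f"could not read {f}: {exc}") from exc
            frames.append(GrayFrame(to_grayscale(arr), index=i))
    elif path.is_file():
        try:
            frames = [
                GrayFrame(to_grayscale(arr), index=i)
                for i, arr in enumerate(iio.imiter(path))
            ]
        except Exception as exc:  # noqa: BLE001
            raise InputError(f"could not decode video {path}: {exc}") from exc
        if not frames:
            raise InputError(f"no frames decoded from {path}")
    else:
        raise InputError(f"{path} is neither a directory nor a file")
    return FrameSequence(frames=frames, fps=fps, base_index=base_index)


def save_sequence(
    seq: FrameSequence | Sequence[GrayFrame],
    directory: str | os.PathLike,
    fmt: str = "png",
    prefix: str = "frame",
) -> list[Path]:
    """Write frames to ``directory`` as numbered image files.

    ``fmt='png'`` writes 8-bit PNGs (values rounded and clipped to 0-255);
    ``fmt='tiff'`` writes float32 TIFFs, which round-trip the stored
    intensities bit-exactly for float32-representable values.
    """
    frames = seq.frames if isinstance(seq, FrameSequence) else list(seq)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        name = f"{prefix}_{i:05d}.{ 'tif' if fmt == 'tiff' else fmt }"
        out = directory / name
        if fmt == "png":
            iio.imwrite(out, np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8))
        elif fmt == "tiff":
            tifffile.imwrite(out, frame.pixels.astype(np.float32))
        else:
            raise InputError(f"unsupported output format {fmt!r}")
        paths.append(out)
    return paths


class PixelScale(NamedTuple):
    """Physical size of one pixel."""

    um_per_px: float
    um_per_px_rounded: int


def pixel_scale(fov_width: float, fov_height: float, width: int, height: int) -> PixelScale:
    """Micrometres per pixel from the field of view (mm) and resolution (px).

    The scale is computed along the width: ``1000 * fov_width / width``.  The
    rounded value is for reporting; the exact value is also returned.  The
    field-of-view height and pixel height are validated for positivity only —
    square pixels are assumed.
    """
    for name, val in (
        ("fov_width", fov_width),
        ("fov_height", fov_height),
        ("width", width),
        ("height", height),
    ):
        if val <= 0:
            raise DomainError(f"{name} must be positive, got {val}")
    exact = 1000.0 * fov_width / width
    return PixelScale(um_per_px=exact, um_per_px_rounded=int(round(exact)))
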