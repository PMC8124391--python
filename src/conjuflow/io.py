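"""Frame-sequence containers and file I/O.

Conventions used throughout the package (stated once here):

* arrays are row-major, 0-based, indexed ``(row=y, col=x)``;
* displacements are reported as ``(dx, dy)`` in pixels with +x rightward
  (increasing column) and +y downward (increasing row);
* frames are processed internally as float in ``[0, 1]``; 8- and 16-bit
  integer input is rescaled by its dtype maximum at read time;
* RGB input is reduced to the green channel at read time (hemoglobin
  absorbs strongly near 530 nm, so the green channel carries the vessel
  contrast).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["FrameSequence", "read_sequence", "write_sequence", "read_mask", "write_mask"]

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


class FormatError(ValueError):
    """Raised for malformed frame stacks (mixed shapes, empty input...)."""


@dataclass
class FrameSequence:
    """An ordered stack of equally sized grayscale frames.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Intensities in [0, 1], float.
    fps : float
        Frames per second of the original acquisition.
    microns_per_pixel : float
        Object-space sampling of each frame.
    frame_indices : ndarray of int, shape (T,)
        Index of each frame in the originally acquired sequence.  Filtering
        steps (blurred-frame rejection, low-correlation rejection) keep this
        so downstream timing uses true acquisition times.
    """

    frames: np.ndarray
    fps: float
    microns_per_pixel: float
    frame_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("frames must be a non-empty (T, H, W) stack")
        if np.any(self.frames < 0):
            raise FormatError("frame intensities must be non-negative")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.n_frames)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if self.frame_indices.shape != (self.n_frames,):
                raise FormatError("frame_indices must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from the first frame."""
        return self.frame_indices / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def subset(self, indices: Sequence[int]) -> "FrameSequence":
        """New sequence holding the given frames, preserving original indices."""
        idx = np.asarray(indices, dtype=int)
        return FrameSequence(
            frames=self.frames[idx].copy(),
            fps=self.fps,
            microns_per_pixel=self.microns_per_pixel,
            frame_indices=self.frame_indices[idx].copy(),
        )


def _to_float(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        # RGB(A): keep the green channel only.
        img = img[..., 1]
    if np.issubdtype(img.dtype, np.integer):
        maxval = np.iinfo(img.dtype).max
        return img.astype(np.float64) / maxval
    return img.astype(np.float64)


def _numeric_key(p: Path) -> tuple:
    nums = re.findall(r"\d+", p.stem)
    return (tuple(int(n) for n in nums), p.name)


def read_sequence(path: str | Path, fps: float = 25.0,
                  microns_per_pixel: float = 3.45 / 3.798) -> FrameSequence:
    """Read a frame sequence from a multi-page TIFF or a directory of frames.

    Directory frames are ordered by the numeric parts of their file names
    (``f_000.png`` ... ``f_009.png``).  RGB input is reduced to the green
    channel; integer data is rescaled to [0, 1] by its dtype maximum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
            key=_numeric_key,
        )
        if not files:
            raise FormatError(f"no frame files in {path}")
        frames = [_to_float(iio.imread(f)) for f in files]
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:  # pages x H x W x channels
            frames = [_to_float(pg) for pg in stack]
        else:
            frames = [_to_float(pg) for pg in stack]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame shapes: {sorted(shapes)}")
    return FrameSequence(np.stack(frames), fps=fps, microns_per_pixel=microns_per_pixel)


def write_sequence(seq: FrameSequence, path: str | Path, dtype=np.uint16) -> None:
    """Write a sequence as a multi-page TIFF (integer, rescaled from [0,1])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    maxval = np.iinfo(dtype).max
    data = np.clip(np.round(seq.frames * maxval), 0, maxval).astype(dtype)
    tifffile.imwrite(path, data)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary vessel mask (0/255 PNG or TIFF) as a boolean array."""
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > (np.iinfo(img.dtype).max // 2 if np.issubdtype(img.dtype, np.integer) else 0.5)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
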