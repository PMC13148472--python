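"""Frame-source abstraction and table I/O.

Supported video containers: multi-page TIFF stacks (``.tif``/``.tiff``),
raw numpy stacks (``.npy``), and directories of numbered PNG frames.  All
are decoded into an (n, h, w) uint8 array.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


class FrameSourceError(ValueError):
    pass


def load_frames(path) -> np.ndarray:
    """Load a grayscale frame stack from a TIFF stack, .npy file, or a
    directory of PNG frames (sorted by name)."""
    p = Path(path)
    if not p.exists():
        raise FrameSourceError(f"no such video input: {p}")
    if p.is_dir():
        files = sorted(q for q in p.iterdir() if q.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FrameSourceError(f"{p}: directory contains no frame images")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
    elif p.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[None]
        frames = np.stack([_to_gray(f) for f in frames])
    elif p.suffix.lower() == ".npy":
        frames = np.load(p)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise FrameSourceError(
            f"{p}: unsupported container {p.suffix!r} (use .tif, .npy, or a PNG directory)"
        )
    if frames.ndim != 3:
        raise FrameSourceError(f"{p}: expected a (n, h, w) grayscale stack")
    if frames.dtype != np.uint8:
        raise FrameSourceError(f"{p}: frames must be 8-bit, got {frames.dtype}")
    return frames


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1).round().astype(np.uint8)
    return img


def save_frames(frames: np.ndarray, path) -> None:
    """Write a stack as TIFF, .npy, or a PNG frame directory."""
    p = Path(path)
    frames = np.asarray(frames, dtype=np.uint8)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, frames, photometric="minisblack")
    elif p.suffix.lower() == ".npy":
        np.save(p, frames)
    else:
        p.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(len(frames))))
        for i, f in enumerate(frames):
            iio.imwrite(p / f"frame_{i:0{width}d}.png", f)
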