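"""Mode-based static background estimation.

The background of a recording is the per-pixel statistical mode of the
sampled frames.  An animal that occupies any given pixel in fewer than half
of the samples never wins the per-pixel vote, so the mode recovers the empty
arena exactly — no explicit foreground masking is needed.  Ties break toward
the smallest intensity, which makes the estimate deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np


class BackgroundError(ValueError):
    pass


@dataclass
class BackgroundImage:
    """Per-pixel mode background with its retained intensity histogram.

    The histogram (shape ``(h*w, 256)``) is kept so the mode can be refreshed
    incrementally as new frames arrive (streaming operation), instead of
    requiring the whole movie again.
    """

    pixels: np.ndarray  # (h, w) uint8
    n_frames_used: int
    sample_stride: int
    histogram: Optional[np.ndarray] = None  # (h*w, 256) uint32

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _accumulate(hist: np.ndarray, frame: np.ndarray) -> None:
    # each pixel contributes exactly one (pixel, value) pair per frame, so
    # plain fancy-index increment is duplicate-free and fast
    flat = frame.reshape(-1)
    hist[np.arange(flat.size), flat] += 1


def _check_frame(frame: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise BackgroundError(f"frames must be uint8 grayscale, got dtype {frame.dtype}")
    if frame.shape != shape:
        raise BackgroundError(f"frame shape {frame.shape} != expected {shape}")
    return frame


def compute_mode_background(
    frames: Iterable[np.ndarray], sample_stride: int = 10
) -> BackgroundImage:
    """Per-pixel mode over every ``sample_stride``-th frame.

    Ties break toward the smallest tied intensity (argmax returns the first
    maximal bin).  Raises on an empty sequence or on shape/dtype mismatch.
    """
    if sample_stride < 1:
        raise BackgroundError("sample_stride must be >= 1")
    hist = None
    shape = None
    n_used = 0
    for i, frame in enumerate(frames):
        if i % sample_stride:
            continue
        if hist is None:
            frame = np.asarray(frame)
            if frame.dtype != np.uint8 or frame.ndim != 2:
                raise BackgroundError("frames must be 2-D uint8 grayscale")
            shape = frame.shape
            hist = np.zeros((frame.size, 256), dtype=np.uint32)
        else:
            frame = _check_frame(frame, shape)
        _accumulate(hist, frame)
        n_used += 1
    if hist is None:
        raise BackgroundError("cannot compute background of an empty frame sequence")
    mode = hist.argmax(axis=1).astype(np.uint8).reshape(shape)
    return BackgroundImage(mode, n_used, sample_stride, hist)


def refresh_background(
    bg: BackgroundImage, new_frames: Iterable[np.ndarray]
) -> BackgroundImage:
    """Fold new samples into the retained histograms and recompute the mode."""
    if bg.histogram is None:
        raise BackgroundError("background has no retained histogram to refresh")
    hist = bg.histogram.copy()
    n_used = bg.n_frames_used
    for frame in new_frames:
        frame = _check_frame(frame, bg.shape)
        _accumulate(hist, frame)
        n_used += 1
    mode = hist.argmax(axis=1).astype(np.uint8).reshape(bg.shape)
    return BackgroundImage(mode, n_used, bg.sample_stride, hist)
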