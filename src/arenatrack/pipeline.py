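"""End-to-end tracking pipeline: background pass, SSIM segmentation pass,
Kalman smoothing, and tidy CSV output.

A run is fully determined by (input frames, RunConfig): the config carries
every tunable default, is serialized next to the outputs, and a manifest
records input checksums so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .background import BackgroundImage, compute_mode_background
from .roi import RoiSet
from .ssim import RasterizedRois, SsimParams, build_context, dpix, segment, ssim_difference
from .tracking import KalmanState, Track, prune_static_tracks, step_track


@dataclass
class RunConfig:
    """Every knob of the pipeline, with its default.

    Units: pixels and frames unless suffixed; thresholds on the 8-bit
    intensity scale or the [0, 1] SSIM-difference scale as appropriate.
    """

    fps: float = 30.0
    # background
    background_stride: int = 10
    bootstrap_frames: int = 300  # streaming mode: frames used to seed the mode
    # ssim
    win_size: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 255.0
    # segmentation
    threshold: float = 0.35
    min_area: float = 4.0
    max_area_frac: float = 0.25
    # dpix
    dpix_threshold: int = 10
    # kalman
    kalman_q: float = 0.01
    kalman_r: float = 1.0
    max_coast: int = 15
    # static-track pruning
    prune_window: int = 30
    prune_min_displacement: float = 1.5
    # y-maze analysis
    debounce_frames: int = 5
    bin_s: float = 600.0
    session_s: float = 3600.0
    heatmap_grid: int = 20
    seed: int = 0

    def ssim_params(self) -> SsimParams:
        return SsimParams(self.win_size, self.k1, self.k2, self.data_range)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in known})


@dataclass
class TrackingResult:
    tracks: dict[str, Track]
    background: BackgroundImage
    table: pd.DataFrame  # frame, time_s, roi_id, x, y, dpix, valid
    stats: dict


def track_frames(
    frames: np.ndarray,
    roi_set: RoiSet,
    config: RunConfig = RunConfig(),
    background: Optional[BackgroundImage] = None,
    prune: bool = True,
) -> TrackingResult:
    """Two-pass offline tracking of an in-memory frame stack.

    Pass 1 estimates the mode background (skipped when one is supplied, e.g.
    a streaming bootstrap); pass 2 computes the SSIM difference image per
    frame, segments one detection per ROI, and advances each ROI's Kalman
    track.  Returns per-ROI tracks and a tidy per-frame table.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, h, w) stack")
    if len(roi_set) == 0:
        raise ValueError("empty ROI set")
    if background is None:
        background = compute_mode_background(frames, config.background_stride)
    ctx = build_context(background.pixels, config.ssim_params())
    rasters = RasterizedRois(roi_set, frames.shape[1:])
    full_masks = {}
    for rid, (sl, m) in rasters.masks.items():
        fm = np.zeros(frames.shape[1:], dtype=bool)
        fm[sl] = m
        full_masks[rid] = fm

    tracks = {roi.id: Track(roi.id) for roi in roi_set}
    filters = {roi.id: KalmanState(q=config.kalman_q, r=config.kalman_r) for roi in roi_set}
    n_detections = 0
    n_coasts = 0
    prev = None
    for t, frame in enumerate(frames):
        diff = ssim_difference(frame, ctx, frame_index=t)
        dets = {
            d.roi_id: d
            for d in segment(
                diff, roi_set,
                threshold=config.threshold,
                min_area=config.min_area,
                max_area_frac=config.max_area_frac,
                rasters=rasters,
            )
        }
        for roi in roi_set:
            dp = 0
            if prev is not None:
                dp = dpix(frame, prev, intensity_threshold=config.dpix_threshold,
                          mask=full_masks[roi.id])
            det = dets.get(roi.id)
            if det is None:
                n_coasts += 1
            else:
                n_detections += 1
            step_track(tracks[roi.id], det, filters[roi.id], t, dp, config.max_coast)
        prev = frame
    track_list = list(tracks.values())
    if prune:
        prune_static_tracks(track_list, config.prune_window, config.prune_min_displacement)
    table = tracks_to_table(tracks, config.fps)
    stats = {
        "n_frames": int(len(frames)),
        "n_rois": len(roi_set),
        "n_detections": int(n_detections),
        "n_missing": int(n_coasts),
        "n_static_pruned": sum(not tr.alive for tr in track_list),
    }
    return TrackingResult(tracks, background, table, stats)


def tracks_to_table(tracks: dict[str, Track], fps: float) -> pd.DataFrame:
    rows = []
    for rid, tr in tracks.items():
        for rec in tr.records:
            rows.append(
                {
                    "frame": rec.frame_index,
                    "time_s": rec.frame_index / fps,
                    "roi_id": rid,
                    "x": rec.smoothed[0],
                    "y": rec.smoothed[1],
                    "dpix": rec.dpix,
                    "valid": rec.valid and tr.alive,
                }
            )
    df = pd.DataFrame(rows, columns=["frame", "time_s", "roi_id", "x", "y", "dpix", "valid"])
    return df.sort_values(["frame", "roi_id"], kind="stable").reset_index(drop=True)


def table_to_tracks(df: pd.DataFrame) -> dict[str, Track]:
    """Rebuild Track objects from a track CSV table."""
    from .tracking import TrackRecord

    tracks: dict[str, Track] = {}
    for rid, sub in df.groupby("roi_id", sort=False):
        tr = Track(str(rid))
        for r in sub.sort_values("frame").itertuples():
            tr.records.append(
                TrackRecord(int(r.frame), None, (float(r.x), float(r.y)),
                            int(r.dpix), bool(r.valid))
            )
        tracks[str(rid)] = tr
    return tracks


def sha256_of_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def write_manifest(path, config: RunConfig, input_checksums: dict, stats: dict) -> None:
    doc = {
        "arenatrack_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": dataclasses.asdict(config),
        "inputs": input_checksums,
        "stats": stats,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
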