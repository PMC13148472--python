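"""Kalman-smoothed per-ROI trajectories and static-track pruning.

One animal lives in each ROI, so data association is trivial: each ROI owns
one track, fed by that ROI's per-frame detection (or a gap).  A constant-
velocity Kalman filter smooths the centroid stream; missing detections are
coasted along the last velocity for a bounded number of frames, after which
the track holds position and its frames are flagged invalid.  Tracks whose
smoothed positions never move more than a minimum displacement within any
short window are discarded as static debris (reflections, stuck detritus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ssim import Detection

_F = np.array(
    [[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
)
_H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)


class TrackingError(ValueError):
    pass


@dataclass
class KalmanState:
    """Constant-velocity state (x, y, vx, vy) with process noise q and
    measurement noise r (px^2), dt = 1 frame."""

    x: np.ndarray = field(default_factory=lambda: np.zeros(4))
    P: np.ndarray = field(default_factory=lambda: np.eye(4) * 500.0)
    q: float = 0.01
    r: float = 1.0
    initialized: bool = False

    def _Q(self) -> np.ndarray:
        # piecewise-constant white acceleration, dt = 1
        q = self.q
        return q * np.array(
            [
                [0.25, 0, 0.5, 0],
                [0, 0.25, 0, 0.5],
                [0.5, 0, 1.0, 0],
                [0, 0.5, 0, 1.0],
            ]
        )

    def predict(self) -> None:
        self.x = _F @ self.x
        self.P = _F @ self.P @ _F.T + self._Q()

    def update(self, z: np.ndarray) -> None:
        if not self.initialized:
            self.x = np.array([z[0], z[1], 0.0, 0.0])
            self.P = np.diag([self.r, self.r, 25.0, 25.0])
            self.initialized = True
            return
        S = _H @ self.P @ _H.T + self.r * np.eye(2)
        K = self.P @ _H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - _H @ self.x)
        self.P = (np.eye(4) - K @ _H) @ self.P

    @property
    def position(self) -> tuple[float, float]:
        return (float(self.x[0]), float(self.x[1]))

    @property
    def velocity(self) -> tuple[float, float]:
        return (float(self.x[2]), float(self.x[3]))


@dataclass
class TrackRecord:
    frame_index: int
    raw: Optional[tuple[float, float]]  # detection centroid, None if missing
    smoothed: tuple[float, float]
    dpix: int = 0
    valid: bool = True


@dataclass
class Track:
    roi_id: str
    records: list[TrackRecord] = field(default_factory=list)
    alive: bool = True
    coast_count: int = 0

    def positions(self, valid_only: bool = False) -> np.ndarray:
        recs = [r for r in self.records if r.valid] if valid_only else self.records
        if not recs:
            return np.empty((0, 2))
        return np.array([r.smoothed for r in recs])

    def frame_indices(self) -> np.ndarray:
        return np.array([r.frame_index for r in self.records], dtype=int)


def step_track(
    track: Track,
    detection: Optional[Detection],
    kf: KalmanState,
    frame_index: int,
    dpix: int = 0,
    max_coast: int = 15,
) -> tuple[Track, KalmanState]:
    """Advance one frame: predict, then measurement-update if a detection is
    present, else coast (prediction only, flagged missing).

    After ``max_coast`` consecutive misses the track freezes in place
    (velocity zeroed) and its records are flagged invalid until a detection
    returns.
    """
    if detection is not None and detection.roi_id != track.roi_id:
        raise TrackingError(
            f"detection for roi {detection.roi_id!r} fed to track {track.roi_id!r}"
        )
    if track.records and frame_index <= track.records[-1].frame_index:
        raise TrackingError("frame indices must be strictly increasing")

    if detection is not None:
        if kf.initialized:
            kf.predict()
        kf.update(np.asarray(detection.centroid, dtype=float))
        track.coast_count = 0
        track.records.append(
            TrackRecord(frame_index, detection.centroid, kf.position, dpix, True)
        )
    else:
        if not kf.initialized:
            # nothing seen yet; no position to report
            track.records.append(
                TrackRecord(frame_index, None, (np.nan, np.nan), dpix, False)
            )
            return track, kf
        track.coast_count += 1
        if track.coast_count <= max_coast:
            kf.predict()
            track.records.append(TrackRecord(frame_index, None, kf.position, dpix, False))
        else:
            kf.x[2:] = 0.0  # hold position
            track.records.append(TrackRecord(frame_index, None, kf.position, dpix, False))
    return track, kf


def prune_static_tracks(
    tracks: list[Track], window: int = 30, min_displacement: float = 1.5
) -> list[Track]:
    """Mark tracks that never move as not-alive and drop them.

    A track is static when no two smoothed positions within ``window`` frames
    of each other are more than ``min_displacement`` apart, anywhere in its
    history.  Equivalently it is kept iff some pair at lag < window exceeds
    the threshold.
    """
    if window < 2:
        raise TrackingError("window must be >= 2")
    kept = []
    for tr in tracks:
        pos = tr.positions()
        pos = pos[~np.isnan(pos).any(axis=1)]
        moved = False
        for lag in range(1, min(window, len(pos))):
            d = np.linalg.norm(pos[lag:] - pos[:-lag], axis=1)
            if d.size and d.max() > min_displacement:
                moved = True
                break
        if moved:
            kept.append(tr)
        else:
            tr.alive = False
    return kept
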