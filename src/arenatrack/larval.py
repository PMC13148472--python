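"""Larval 96-well behavioral metrics: activity, bouts, stimulus responses.

All metrics derive from two per-frame signals already present on a track:
the delta-pixel count (dpix — pixels whose intensity changed beyond a
threshold between consecutive frames, the classic larval activity proxy)
and the smoothed centroid.  A stimulus schedule file supplies event onsets
(dark flashes, light flashes, acoustic stimuli) for response alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tracking import Track

STIMULUS_KINDS = ("dark_flash", "light_flash", "acoustic")


class LarvalError(ValueError):
    pass


@dataclass
class StimulusEvent:
    kind: str
    onset_s: float
    duration_s: float
    block: str = ""


@dataclass
class StimulusSchedule:
    """Times and durations of stimuli; onsets must be non-decreasing."""

    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise LarvalError("stimulus onsets must be non-decreasing")
        if any(e.duration_s <= 0 for e in self.events):
            raise LarvalError("stimulus durations must be > 0")

    @classmethod
    def from_csv(cls, path) -> "StimulusSchedule":
        df = pd.read_csv(path)
        need = {"kind", "onset_s", "duration_s"}
        if not need.issubset(df.columns):
            raise LarvalError(f"schedule CSV must have columns {sorted(need)}")
        events = [
            StimulusEvent(
                str(r.kind), float(r.onset_s), float(r.duration_s),
                str(getattr(r, "block", "")),
            )
            for r in df.itertuples()
        ]
        return cls(events)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {"kind": e.kind, "onset_s": e.onset_s,
                 "duration_s": e.duration_s, "block": e.block}
                for e in self.events
            ]
        ).to_csv(path, index=False)


def _dpix_series(track: Track) -> np.ndarray:
    return np.array([r.dpix for r in track.records], dtype=float)


def active_seconds(
    track: Track, fps: float = 30.0, activity_threshold: float = 3.0
) -> pd.Series:
    """Active-second counts per clock hour.

    A second is active iff the summed dpix of its frames exceeds
    ``activity_threshold``.  Tracks shorter than one second yield an empty
    series.
    """
    if fps <= 0:
        raise LarvalError("fps must be > 0")
    dp = _dpix_series(track)
    frames = track.frame_indices()
    if len(frames) == 0 or (frames[-1] + 1) < fps:
        return pd.Series(dtype=int, name="active_seconds")
    secs = (frames / fps).astype(int)
    per_sec = pd.Series(dp).groupby(secs).sum()
    active = per_sec > activity_threshold
    hours = active.index // 3600
    out = active.groupby(hours).sum().astype(int)
    out.index.name = "hour"
    out.name = "active_seconds"
    return out


@dataclass
class Bout:
    start_frame: int
    end_frame: int  # last supra-threshold frame
    displacement: float  # |pos(end) - pos(start)| in px


def detect_bouts(
    track: Track,
    fps: float = 30.0,
    start_threshold: float = 2.0,
    quiescence_frames: int = 5,
) -> list[Bout]:
    """Movement bouts: dpix rises above ``start_threshold`` and the bout ends
    after ``quiescence_frames`` consecutive frames at or below it.

    Displacement is the straight-line distance between the smoothed positions
    at bout start and bout end.
    """
    if start_threshold <= 0 or quiescence_frames <= 0:
        raise LarvalError("thresholds must be > 0")
    dp = _dpix_series(track)
    pos = track.positions()
    bouts: list[Bout] = []
    in_bout = False
    start = last_active = 0
    quiet = 0
    for i, v in enumerate(dp):
        if v > start_threshold:
            if not in_bout:
                in_bout, start = True, i
            last_active, quiet = i, 0
        elif in_bout:
            quiet += 1
            if quiet >= quiescence_frames:
                bouts.append(_close_bout(track, pos, start, last_active))
                in_bout = False
    if in_bout:
        bouts.append(_close_bout(track, pos, start, last_active))
    return bouts


def _close_bout(track: Track, pos: np.ndarray, start: int, end: int) -> Bout:
    d = float(np.linalg.norm(pos[end] - pos[start]))
    frames = track.frame_indices()
    return Bout(int(frames[start]), int(frames[end]), d)


def bout_displacement(bouts: Sequence[Bout]) -> Optional[float]:
    """Mean start-to-end displacement; None (missing) when there are no bouts."""
    if not bouts:
        return None
    return float(np.mean([b.displacement for b in bouts]))


@dataclass
class EventResponse:
    kind: str
    onset_s: float
    block: str
    trace: np.ndarray  # dpix over [onset - window, onset + window]
    trace_offsets_s: np.ndarray
    displacement: float  # path length of smoothed positions during the stimulus


def stimulus_response(
    track: Track,
    schedule: StimulusSchedule,
    window_s: float = 2.0,
    fps: float = 30.0,
) -> tuple[list[EventResponse], int]:
    """Frame-aligned dpix traces around each stimulus plus per-event response
    displacement (path length of the smoothed trajectory during the stimulus).

    Events whose window falls outside the track span are skipped; the second
    return value counts the skips.
    """
    frames = track.frame_indices()
    dp = _dpix_series(track)
    pos = track.positions()
    valid = np.array([r.valid for r in track.records], dtype=bool)
    if len(frames) == 0:
        return [], len(schedule.events)
    f0, f1 = frames[0], frames[-1]
    half = int(round(window_s * fps))
    responses = []
    skipped = 0
    for ev in schedule.events:
        onset_f = int(round(ev.onset_s * fps))
        end_f = int(round((ev.onset_s + ev.duration_s) * fps))
        if onset_f - half < f0 or onset_f + half > f1 or end_f > f1:
            skipped += 1
            continue
        lo = onset_f - half - f0
        hi = onset_f + half - f0
        trace = dp[lo : hi + 1]
        offsets = (np.arange(lo, hi + 1) + f0 - onset_f) / fps
        seg = pos[onset_f - f0 : end_f - f0 + 1]
        seg_ok = valid[onset_f - f0 : end_f - f0 + 1]
        seg = seg[seg_ok]
        disp = float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum()) if len(seg) > 1 else 0.0
        responses.append(
            EventResponse(ev.kind, ev.onset_s, ev.block, trace.copy(), offsets, disp)
        )
    return responses, skipped


def metric_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Tidy long-format metric table: one row per (fish, interval, metric)."""
    df = pd.DataFrame(rows, columns=["fish", "interval", "metric", "value"])
    if df.duplicated(["fish", "interval", "metric"]).any():
        raise LarvalError("duplicate (fish, interval, metric) rows")
    return df
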