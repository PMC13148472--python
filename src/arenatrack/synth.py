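"""Ground-truthed synthetic scenes: rendered videos and scripted trajectories.

Every pipeline stage is testable without external recordings.  Scenes mimic
IR-backlit arenas: a uniform light background with one dark Gaussian-profile
blob per ROI (fish appear dark under infrared backlighting), plus i.i.d.
Gaussian pixel noise.  Scripts carry the exact per-frame centers, so
recovery error is measurable to the pixel.

Two arena families are provided: a 96-well plate with per-well sinusoidal
swim paths, and equilateral three-armed Y-mazes in which a scripted turn
sequence is converted into a piecewise-linear path through arm waypoints
(the right inverse of entry/turn extraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .roi import GridSpec, PolygonRoi, RoiSet, generate_grid
from .ymaze import MazeDef


class ScriptError(ValueError):
    pass


# ---------------------------------------------------------------------------
# blob scripts and rendering


@dataclass
class BlobScript:
    """Per-frame blob centers for one ROI, with appearance parameters."""

    roi_id: str
    centers: np.ndarray  # (n_frames, 2) float (x, y)
    radius: float = 3.0
    blob_intensity: float = 47.0
    background_intensity: float = 200.0
    noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.radius < 2:
            raise ScriptError("blob radius must be >= 2 px")
        if not 0 < self.contrast <= 1:
            raise ScriptError("contrast must lie in (0, 1]")

    @property
    def contrast(self) -> float:
        return abs(self.blob_intensity - self.background_intensity) / 255.0


def render_video(
    scripts: Sequence[BlobScript],
    roi_set: RoiSet,
    n_frames: int,
    fps: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render 8-bit grayscale frames plus an exact ground-truth table.

    One script per ROI; a script whose center ever leaves its ROI is a
    script error.  Same seed -> bit-identical video.
    """
    if roi_set.frame_shape is None:
        raise ScriptError("roi_set must carry a frame_shape to render against")
    h, w = roi_set.frame_shape
    bgs = {s.background_intensity for s in scripts}
    if len(bgs) > 1:
        raise ScriptError("all scripts must share one background intensity")
    bg = bgs.pop() if bgs else 200.0
    for s in scripts:
        roi = roi_set[s.roi_id]
        if len(s.centers) < n_frames:
            raise ScriptError(f"script {s.roi_id!r} shorter than n_frames")
        inside = roi.contains_many(s.centers[:n_frames, 0], s.centers[:n_frames, 1])
        if not inside.all():
            f = int(np.nonzero(~inside)[0][0])
            raise ScriptError(f"script {s.roi_id!r}: blob leaves its ROI at frame {f}")
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    truth = []
    for t in range(n_frames):
        scene = np.full((h, w), bg, dtype=np.float64)
        for s in scripts:
            cx, cy = s.centers[t]
            _stamp_blob(scene, cx, cy, s.radius, s.blob_intensity - s.background_intensity)
            truth.append({"frame": t, "roi_id": s.roi_id, "x": cx, "y": cy})
        sigmas = {s.noise_sigma for s in scripts}
        sigma = sigmas.pop() if len(sigmas) == 1 else max(sigmas, default=0.0)
        if sigma > 0:
            scene = scene + rng.normal(0.0, sigma, size=scene.shape)
        frames[t] = np.clip(np.rint(scene), 0, 255).astype(np.uint8)
    return frames, pd.DataFrame(truth)


def _stamp_blob(scene: np.ndarray, cx: float, cy: float, radius: float, depth: float) -> None:
    # Gaussian intensity profile, scale = radius / 2, stamped on a local patch
    sig = radius / 2.0
    ext = int(math.ceil(3.5 * sig))
    h, w = scene.shape
    r0 = max(int(cy) - ext, 0)
    r1 = min(int(cy) + ext + 1, h)
    c0 = max(int(cx) - ext, 0)
    c1 = min(int(cx) + ext + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    scene[r0:r1, c0:c1] += depth * np.exp(-d2 / (2 * sig**2))


# ---------------------------------------------------------------------------
# 96-well plate preset


@dataclass
class PlateScene:
    roi_set: RoiSet
    scripts: list[BlobScript]
    frames: np.ndarray
    truth: pd.DataFrame


def plate96_scene(
    n_frames: int = 240,
    contrast: float = 0.6,
    noise_sigma: float = 2.0,
    seed: int = 1,
    well_px: int = 40,
    margin: int = 10,
    fps: float = 30.0,
    amplitude: float = 12.0,
    background_intensity: float = 200.0,
) -> PlateScene:
    """A 96-well plate (12 x 8 wells) with one swimming blob per well.

    Paths are Lissajous figures with per-well seeded phases and
    incommensurate x/y periods, so blobs sweep most of the well and occupy
    no pixel in a majority of frames (keeping the mode background clean,
    as roaming fish do in real wells)."""
    cols, rows = 12, 8
    x1 = margin + cols * well_px
    y1 = margin + rows * well_px
    spec = GridSpec(cols - 1, rows - 1, (margin, margin, x1, y1))
    roi_set = generate_grid(spec)
    roi_set.frame_shape = (y1 + margin, x1 + margin)
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    scripts = []
    blob = background_intensity - 255.0 * contrast
    for roi in roi_set:
        cx, cy = roi.centroid
        phase = rng.uniform(0, 2 * np.pi, size=2)
        px = rng.uniform(55, 80)
        py = rng.uniform(95, 140)
        xs = cx + amplitude * np.sin(2 * np.pi * t / px + phase[0])
        ys = cy + amplitude * np.sin(2 * np.pi * t / py + phase[1])
        scripts.append(
            BlobScript(
                roi.id,
                np.column_stack([xs, ys]),
                radius=3.0,
                blob_intensity=blob,
                background_intensity=background_intensity,
                noise_sigma=noise_sigma,
            )
        )
    frames, truth = render_video(scripts, roi_set, n_frames, fps, seed=seed + 1)
    return PlateScene(roi_set, scripts, frames, truth)


# ---------------------------------------------------------------------------
# Y-maze geometry and turn scripts


def make_ymaze(
    center: tuple[float, float] = (60.0, 60.0),
    arm_length: float = 38.0,
    arm_width: float = 18.0,
    center_radius: float = 12.0,
    habituation_arm: int = 0,
) -> MazeDef:
    """Equilateral three-armed maze: arms 0, 1, 2 at 120-degree spacing
    (counterclockwise labeling) around a 12-gon center zone."""
    cx, cy = center
    arms = []
    for i in range(3):
        th = math.radians(90.0 + 120.0 * i)
        ux, uy = math.cos(th), math.sin(th)
        nx, ny = -uy, ux
        hw = arm_width / 2.0
        r0, r1 = center_radius, center_radius + arm_length
        verts = [
            (cx + r0 * ux + hw * nx, cy + r0 * uy + hw * ny),
            (cx + r1 * ux + hw * nx, cy + r1 * uy + hw * ny),
            (cx + r1 * ux - hw * nx, cy + r1 * uy - hw * ny),
            (cx + r0 * ux - hw * nx, cy + r0 * uy - hw * ny),
        ]
        arms.append(PolygonRoi(f"arm{i}", verts))
    # 12-gon rotated so no vertex lies on an arm axis -> zone interiors disjoint
    angles = np.radians(15.0 + np.arange(12) * 30.0)
    ring = np.column_stack(
        [cx + center_radius * np.cos(angles), cy + center_radius * np.sin(angles)]
    )
    return MazeDef(arms, PolygonRoi("center", ring), habituation_arm)


def maze_roi_set(maze: MazeDef, frame_shape: tuple[int, int], pad: float = 4.0) -> RoiSet:
    """One tracking ROI covering the whole maze (one fish per maze)."""
    x0, y0, x1, y1 = maze.bounds()
    x0, y0 = max(x0 - pad, 0), max(y0 - pad, 0)
    x1, y1 = min(x1 + pad, frame_shape[1]), min(y1 + pad, frame_shape[0])
    roi = PolygonRoi("maze", [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    return RoiSet([roi], frame_shape)


@dataclass
class TurnScript:
    """A scripted L/R turn sequence realized as maze navigation."""

    turns: str
    maze: MazeDef
    dwell_s: float = 0.4
    travel_s: float = 0.5  # arm tip -> center -> next arm tip

    def __post_init__(self) -> None:
        if set(self.turns) - {"L", "R"}:
            raise ScriptError("turns must be a string over {L, R}")
        if self.dwell_s <= 0:
            raise ScriptError("dwell must be > 0")

    def entry_sequence(self) -> list[int]:
        entries = [self.maze.habituation_arm]
        for t in self.turns:
            a = entries[-1]
            entries.append((a + 1) % 3 if t == "L" else (a + 2) % 3)
        return entries


def _arm_tip(maze: MazeDef, arm: int, frac: float = 0.72) -> np.ndarray:
    v = maze.arms[arm].vertices
    tip_edge_mid = (v[1] + v[2]) / 2.0
    base_mid = (v[0] + v[3]) / 2.0
    return base_mid + frac * (tip_edge_mid - base_mid)


def path_from_turns(
    script: TurnScript, fps: float = 30.0, debounce_frames: int = 5
) -> BlobScript:
    """Piecewise-linear path realizing exactly the scripted entry sequence.

    Each arm visit dwells at a waypoint deep in the arm for longer than the
    entry debounce, and travel legs pass through the center of the maze, so
    ``turns_from_entries(detect_entries(path)) == script.turns``.
    """
    if script.dwell_s * fps < debounce_frames:
        raise ScriptError("dwell shorter than the entry debounce")
    maze = script.maze
    entries = script.entry_sequence()
    center = np.asarray(maze.center.centroid)
    dwell_n = max(int(round(script.dwell_s * fps)), debounce_frames + 1)
    leg_n = max(int(round(script.travel_s * fps / 2)), 2)
    points = [np.repeat(_arm_tip(maze, entries[0])[None, :], dwell_n, axis=0)]
    for arm in entries[1:]:
        prev_tip = points[-1][-1]
        tip = _arm_tip(maze, arm)
        out_leg = np.linspace(prev_tip, center, leg_n, endpoint=False)
        in_leg = np.linspace(center, tip, leg_n, endpoint=False)
        dwell = np.repeat(tip[None, :], dwell_n, axis=0)
        points.extend([out_leg, in_leg, dwell])
    centers = np.vstack(points)
    return BlobScript("maze", centers, radius=3.0)


def random_turns(n: int, p_alternate: float = 0.5, seed: int = 0) -> str:
    """Markov turn string: first turn fair; each subsequent turn differs from
    the previous with probability ``p_alternate`` (0.5 = i.i.d. fair turns)."""
    if not 0.0 <= p_alternate <= 1.0:
        raise ScriptError("p_alternate must be in [0, 1]")
    if n <= 0:
        return ""
    rng = np.random.default_rng(seed)
    turns = [int(rng.random() < 0.5)]
    flips = rng.random(n - 1) < p_alternate
    for f in flips:
        turns.append(turns[-1] ^ int(f))
    return "".join("LR"[t] for t in turns)


# ---------------------------------------------------------------------------
# multi-maze plate


@dataclass
class YmazeScene:
    mazes: list[MazeDef]
    roi_set: RoiSet  # one tracking ROI per maze, ids maze0..maze{n-1}
    scripts: list[BlobScript]
    turn_strings: list[str]
    frames: np.ndarray
    truth: pd.DataFrame


def ymaze_plate_scene(
    turn_strings: Sequence[str],
    n_cols: int = 4,
    contrast: float = 0.6,
    noise_sigma: float = 2.0,
    seed: int = 1,
    fps: float = 30.0,
    tile_px: int = 120,
    dwell_s: float = 0.4,
    background_intensity: float = 200.0,
) -> YmazeScene:
    """A plate of independent Y-mazes, one scripted fish per maze.

    All sessions are padded to the longest path by letting finished fish
    rest at their final waypoint.
    """
    n = len(turn_strings)
    rows = math.ceil(n / n_cols)
    h, w = rows * tile_px, min(n, n_cols) * tile_px
    blob = background_intensity - 255.0 * contrast
    mazes, rois, scripts = [], [], []
    paths = []
    for i, turns in enumerate(turn_strings):
        r, c = divmod(i, n_cols)
        cx = c * tile_px + tile_px / 2.0
        cy = r * tile_px + tile_px / 2.0
        maze = make_ymaze((cx, cy))
        path = path_from_turns(TurnScript(turns, maze, dwell_s=dwell_s), fps=fps)
        mazes.append(maze)
        paths.append(path.centers)
        x0, y0, x1, y1 = maze.bounds()
        pad = 4.0
        rois.append(
            PolygonRoi(
                f"maze{i}",
                [(x0 - pad, y0 - pad), (x1 + pad, y0 - pad),
                 (x1 + pad, y1 + pad), (x0 - pad, y1 + pad)],
            )
        )
    n_frames = max(len(p) for p in paths)
    roi_set = RoiSet(rois, (h, w))
    for i, p in enumerate(paths):
        if len(p) < n_frames:
            p = np.vstack([p, np.repeat(p[-1][None, :], n_frames - len(p), axis=0)])
        scripts.append(
            BlobScript(
                f"maze{i}", p, radius=3.0, blob_intensity=blob,
                background_intensity=background_intensity, noise_sigma=noise_sigma,
            )
        )
    frames, truth = render_video(scripts, roi_set, n_frames, fps, seed=seed + 1)
    return YmazeScene(mazes, roi_set, scripts, list(turn_strings), frames, truth)
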