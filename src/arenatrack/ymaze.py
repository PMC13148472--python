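"""Free-movement-pattern Y-maze analysis: entries, turns, tetragrams.

A fish exploring an equilateral three-armed maze produces a sequence of arm
entries, which this module reduces to a string of left/right turns.  With
arms labeled 0, 1, 2 counterclockwise, the transition a -> (a+1) mod 3 is a
left turn and a -> (a+2) mod 3 a right turn.  Overlapping windows of four
consecutive turns (tetragrams) summarize navigation strategy: under fair,
independent turns each of the 16 words has probability 1/16, so the two
pure alternation words LRLR and RLRL together occur 12.5% of the time —
the chance level against which spontaneous alternation is tested.

The L/R convention is arbitrary: mirroring the maze swaps the letters of
every tetragram but leaves alternation percentage and totals unchanged, and
the 16 words collapse into 8 mirror-pair classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .roi import PolygonRoi, RoiSet, load_rois_document, RoiFileError
from .stats import bh_fdr, one_sample_t
from .tracking import Track

ALTERNATION_WORDS = ("LRLR", "RLRL")
ALL_TETRAGRAMS = tuple("".join(w) for w in itertools.product("LR", repeat=4))


class YMazeError(ValueError):
    pass


@dataclass
class MazeDef:
    """Three arm polygons (labels 0,1,2 counterclockwise), a center zone,
    and the habituation arm the fish acclimates in."""

    arms: list[PolygonRoi]  # index == label
    center: PolygonRoi
    habituation_arm: int = 0

    def __post_init__(self) -> None:
        if len(self.arms) != 3:
            raise YMazeError("a Y-maze needs exactly 3 arms")
        if self.habituation_arm not in (0, 1, 2):
            raise YMazeError("habituation_arm must be 0, 1 or 2")

    def zone_of(self, point: tuple[float, float]) -> Optional[object]:
        """Arm label (int), 'center', or None."""
        for i, arm in enumerate(self.arms):
            if arm.contains(point):
                return i
        if self.center.contains(point):
            return "center"
        return None

    def arm_membership(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorized per-frame arm label; -1 where not inside any arm."""
        out = np.full(len(xs), -1, dtype=int)
        ok = np.isfinite(xs) & np.isfinite(ys)
        for i, arm in enumerate(self.arms):
            inside = np.zeros(len(xs), dtype=bool)
            inside[ok] = arm.contains_many(xs[ok], ys[ok])
            out[inside & (out == -1)] = i
        return out

    def bounds(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(a.bounds for a in self.arms + [self.center]))
        return (min(xs0), min(ys0), max(xs1), max(ys1))


def maze_from_roi_file(path) -> MazeDef:
    """Load a MazeDef from a ROI JSON file with reserved ids
    arm0/arm1/arm2/center and a top-level "habituation_arm" field."""
    doc = load_rois_document(path)
    by_id = {rec["id"]: rec for rec in doc.get("rois", [])}
    missing = [i for i in ("arm0", "arm1", "arm2", "center") if i not in by_id]
    if missing:
        raise RoiFileError(f"{path}: maze file lacks required ids {missing}")
    arms = [
        PolygonRoi(f"arm{i}", np.asarray(by_id[f"arm{i}"]["vertices"], float))
        for i in range(3)
    ]
    center = PolygonRoi("center", np.asarray(by_id["center"]["vertices"], float))
    return MazeDef(arms, center, int(doc.get("habituation_arm", 0)))


@dataclass
class TurnRecord:
    """Timestamped L/R turn sequence for one fish."""

    turns: str
    times: np.ndarray  # seconds, one per turn, strictly increasing
    entries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.turns):
            raise YMazeError("times and turns must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise YMazeError("turn times must be strictly increasing")


def detect_entries(
    track: Track, maze: MazeDef, debounce_frames: int = 5, fps: float = 30.0
) -> tuple[list[int], np.ndarray]:
    """Arm entry sequence with entry times (s) from a smoothed track.

    An entry into arm ``a`` is recorded once the centroid has been inside
    arm ``a`` for ``debounce_frames`` consecutive frames and ``a`` differs
    from the last recorded arm.  Dwelling in the center zone (or brief
    boundary excursions shorter than the debounce) does not end an arm
    occupancy.
    """
    if debounce_frames < 1:
        raise YMazeError("debounce_frames must be >= 1")
    pos = track.positions(valid_only=False)
    valid = np.array([r.valid for r in track.records], dtype=bool)
    frames = track.frame_indices()
    if len(pos) == 0:
        return [], np.empty(0)
    xs, ys = pos[:, 0], pos[:, 1]
    arm_of_frame = maze.arm_membership(xs, ys)
    arm_of_frame[~valid] = -1

    entries: list[int] = []
    times: list[float] = []
    candidate = -1
    count = 0
    for arm, fi in zip(arm_of_frame, frames):
        if arm == -1:
            candidate, count = -1, 0
            continue
        if arm == candidate:
            count += 1
        else:
            candidate, count = arm, 1
        if count == debounce_frames and (not entries or entries[-1] != arm):
            entries.append(int(arm))
            times.append(fi / fps)
    return entries, np.asarray(times)


def turns_from_entries(
    entries: Sequence[int], times: Optional[Sequence[float]] = None
) -> TurnRecord:
    """Map arm transitions to turns: a -> (a+1) mod 3 is 'L', a -> (a+2)
    mod 3 is 'R'.  The first entry yields no turn."""
    entries = list(entries)
    if times is None:
        times = np.arange(len(entries), dtype=float)
    times = np.asarray(times, dtype=float)
    turns = []
    turn_times = []
    for i in range(1, len(entries)):
        a, b = entries[i - 1], entries[i]
        if b == a:
            raise YMazeError("consecutive identical arm entries are impossible")
        turns.append("L" if b == (a + 1) % 3 else "R")
        turn_times.append(times[i])
    return TurnRecord("".join(turns), np.asarray(turn_times), entries)


@dataclass
class TetragramTable:
    counts: dict[str, int]
    total: int
    alternation_percent: Optional[float]
    times: np.ndarray = field(default_factory=lambda: np.empty(0))  # 4th-turn times

    def mirror_class_counts(self) -> dict[frozenset, int]:
        out: dict[frozenset, int] = {}
        for w, c in self.counts.items():
            key = mirror_class(w)
            out[key] = out.get(key, 0) + c
        return out


def mirror_word(word: str) -> str:
    return word.translate(str.maketrans("LR", "RL"))


def mirror_class(word: str) -> frozenset:
    return frozenset({word, mirror_word(word)})


def tetragram_mirror_classes() -> list[frozenset]:
    """The L<->R mirror-pair classes of the 16 tetragrams (there are 8)."""
    return sorted({mirror_class(w) for w in ALL_TETRAGRAMS}, key=lambda s: min(s))


def tetragrams(record: TurnRecord) -> TetragramTable:
    """Overlapping (stride-1) windows of four consecutive turns.

    Each tetragram is timestamped by its fourth turn.  With fewer than four
    turns the total is 0 and the alternation percentage undefined (None).
    """
    turns = record.turns
    counts = {w: 0 for w in ALL_TETRAGRAMS}
    n = max(0, len(turns) - 3)
    for i in range(n):
        counts[turns[i : i + 4]] += 1
    times = record.times[3:] if n else np.empty(0)
    if n == 0:
        return TetragramTable(counts, 0, None, times)
    alt = 100.0 * sum(counts[w] for w in ALTERNATION_WORDS) / n
    return TetragramTable(counts, n, alt, times)


def bin_tetragrams(
    record: TurnRecord, bin_s: float = 600.0, session_s: float = 3600.0
) -> pd.DataFrame:
    """Per-bin tetragram totals and alternation percentages.

    Bins partition [0, session_s); a tetragram belongs to the bin containing
    its fourth-turn time.  Empty bins report total 0 and a missing (NaN)
    alternation percentage.
    """
    if session_s % bin_s:
        raise YMazeError("bin_s must divide session_s")
    n_bins = int(round(session_s / bin_s))
    table = tetragrams(record)
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_s, (b + 1) * bin_s
        sel = (table.times >= lo) & (table.times < hi)
        idx = np.nonzero(sel)[0]
        total = len(idx)
        if total:
            words = [record.turns[i : i + 4] for i in idx]
            alt = 100.0 * sum(w in ALTERNATION_WORDS for w in words) / total
        else:
            alt = np.nan
        rows.append({"bin": b, "t_start_s": lo, "total": total, "alternation_percent": alt})
    return pd.DataFrame(rows)


def spatial_metrics(
    track: Track,
    maze: MazeDef,
    grid_shape: tuple[int, int] = (20, 20),
    fps: float = 30.0,
) -> dict:
    """Occupancy heatmap, habituation-arm time, and velocity summary.

    heatmap: 2-D histogram of valid smoothed positions over the maze
    bounding box, normalized to sum 1.  habituation_arm_seconds: time the
    centroid spends inside the habituation arm.  velocity: per-frame
    displacement x fps, summarized by median and IQR.
    """
    if grid_shape[0] < 1 or grid_shape[1] < 1:
        raise YMazeError("grid_shape must be positive")
    pos = track.positions(valid_only=True)
    if len(pos) == 0:
        return {
            "heatmap": None,
            "habituation_arm_seconds": None,
            "velocity_px_per_s": None,
            "velocity_median": None,
            "velocity_iqr": None,
        }
    x0, y0, x1, y1 = maze.bounds()
    heat, _, _ = np.histogram2d(
        pos[:, 1], pos[:, 0], bins=grid_shape, range=[[y0, y1], [x0, x1]]
    )
    heat /= heat.sum()
    arm = maze.arm_membership(pos[:, 0], pos[:, 1])
    hab_s = float((arm == maze.habituation_arm).sum()) / fps
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    vel = steps * fps
    q1, med, q3 = (np.percentile(vel, [25, 50, 75]) if len(vel) else (np.nan,) * 3)
    return {
        "heatmap": heat,
        "habituation_arm_seconds": hab_s,
        "velocity_px_per_s": vel,
        "velocity_median": float(med),
        "velocity_iqr": float(q3 - q1),
    }


def chance_tests(per_bin_percents: dict[int, Sequence[float]], chance: float = 12.5) -> pd.DataFrame:
    """Per-bin one-sample t-tests of alternation percentages against chance
    (12.5% = 2/16 under fair independent turns), BH-FDR adjusted across bins.

    Bins with fewer than two values are skipped (reported missing); a bin
    with zero variance away from chance is degenerate and flagged.
    """
    rows = []
    for b in sorted(per_bin_percents):
        vals = np.asarray(
            [v for v in per_bin_percents[b] if np.isfinite(v)], dtype=float
        )
        if len(vals) < 2:
            rows.append(
                {"bin": b, "n": len(vals), "mean": vals.mean() if len(vals) else np.nan,
                 "t": np.nan, "p": np.nan, "degenerate": False}
            )
            continue
        t, p = one_sample_t(vals, chance)
        rows.append(
            {"bin": b, "n": len(vals), "mean": float(vals.mean()), "t": t, "p": p,
             "degenerate": not np.isfinite(t) or (np.isnan(p) and t != 0)}
        )
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["p_fdr"] = np.nan
    if tested.any():
        df.loc[tested, "p_fdr"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    return df
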