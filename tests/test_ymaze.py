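"""Y-maze entries, turns, tetragrams, binning, spatial metrics, chance tests."""

import numpy as np
import pytest

from arenatrack.synth import TurnScript, make_ymaze, path_from_turns, random_turns
from arenatrack.ymaze import (
    ALL_TETRAGRAMS,
    TetragramTable,
    TurnRecord,
    YMazeError,
    bin_tetragrams,
    chance_tests,
    detect_entries,
    mirror_word,
    spatial_metrics,
    tetragram_mirror_classes,
    tetragrams,
    turns_from_entries,
)
from conftest import track_from_path

FPS = 30.0


def scripted_track(maze, turns, dwell_s=0.4):
    path = path_from_turns(TurnScript(turns, maze, dwell_s=dwell_s), fps=FPS)
    return track_from_path(path.centers, fps=FPS)


class TestEntries:
    def test_scripted_visits_recovered(self, maze):
        tr = scripted_track(maze, "LL")  # habituation arm 0 -> 1 -> 2
        entries, times = detect_entries(tr, maze, 5, FPS)
        assert entries == [0, 1, 2]
        assert len(times) == 3 and (np.diff(times) > 0).all()

    def test_boundary_oscillation_debounced(self, maze):
        """Sub-debounce excursions into a neighboring arm record no entry."""
        a0 = np.asarray(maze.arms[0].polygon.representative_point().coords[0])
        a1 = np.asarray(maze.arms[1].polygon.representative_point().coords[0])
        path = [a0] * 30
        for _ in range(6):
            path += [a1] * 3 + [a0] * 3  # 3 frames < debounce of 5
        tr = track_from_path(path, fps=FPS)
        entries, _ = detect_entries(tr, maze, 5, FPS)
        assert entries == [0]

    def test_center_dwell_does_not_end_occupancy(self, maze):
        a0 = np.asarray(maze.arms[0].polygon.representative_point().coords[0])
        c = np.asarray(maze.center.centroid)
        path = [a0] * 20 + [c] * 40 + [a0] * 20
        tr = track_from_path(path, fps=FPS)
        entries, _ = detect_entries(tr, maze, 5, FPS)
        assert entries == [0]

    def test_never_in_any_arm(self, maze):
        c = np.asarray(maze.center.centroid)
        tr = track_from_path([c] * 50, fps=FPS)
        entries, times = detect_entries(tr, maze, 5, FPS)
        assert entries == [] and len(times) == 0


class TestTurns:
    def test_counterclockwise_progression_is_all_left(self):
        assert turns_from_entries([0, 1, 2, 0, 1]).turns == "LLLL"

    def test_alternation_pattern(self):
        assert turns_from_entries([0, 1, 0, 1, 0]).turns == "LRLR"

    def test_single_entry_no_turns(self):
        assert turns_from_entries([0]).turns == ""

    def test_identical_consecutive_entries_rejected(self):
        with pytest.raises(YMazeError):
            turns_from_entries([0, 0])

    def test_rotation_symmetry(self):
        """Cyclically relabeling arms leaves the turn string unchanged."""
        rng = np.random.default_rng(0)
        entries = [0]
        for _ in range(40):
            entries.append((entries[-1] + rng.integers(1, 3)) % 3)
        base = turns_from_entries(entries).turns
        for shift in (1, 2):
            rot = [(e + shift) % 3 for e in entries]
            assert turns_from_entries(rot).turns == base

    def test_mirror_symmetry(self):
        """Reflecting the maze (swapping two arm labels) letter-swaps the
        turn string and leaves alternation statistics unchanged."""
        rng = np.random.default_rng(1)
        entries = [0]
        for _ in range(60):
            entries.append((entries[-1] + rng.integers(1, 3)) % 3)
        swap = {0: 0, 1: 2, 2: 1}
        rec = turns_from_entries(entries)
        mir = turns_from_entries([swap[e] for e in entries])
        assert mir.turns == mirror_word(rec.turns)
        ta, tm = tetragrams(rec), tetragrams(mir)
        assert ta.total == tm.total
        assert ta.alternation_percent == pytest.approx(tm.alternation_percent)
        for w in ALL_TETRAGRAMS:
            assert ta.counts[w] == tm.counts[mirror_word(w)]


class TestTetragrams:
    def test_overlapping_windows(self):
        t = tetragrams(TurnRecord("LRLRLR", np.arange(6.0)))
        assert t.total == 3
        assert t.counts["LRLR"] == 2 and t.counts["RLRL"] == 1
        assert t.alternation_percent == pytest.approx(100.0)

    def test_constant_turns(self):
        t = tetragrams(TurnRecord("LLLLL", np.arange(5.0)))
        assert t.total == 2 and t.counts["LLLL"] == 2
        assert t.alternation_percent == 0.0

    def test_too_short_undefined(self):
        t = tetragrams(TurnRecord("LRL", np.arange(3.0)))
        assert t.total == 0 and t.alternation_percent is None

    def test_counts_sum_to_total(self):
        turns = random_turns(200, 0.5, seed=5)
        t = tetragrams(TurnRecord(turns, np.arange(200.0)))
        assert sum(t.counts.values()) == t.total == 197

    def test_mirror_classes_are_eight_pairs(self):
        classes = tetragram_mirror_classes()
        assert len(classes) == 8
        assert all(len(c) == 2 for c in classes)
        assert set().union(*classes) == set(ALL_TETRAGRAMS)
        assert frozenset({"LRLR", "RLRL"}) in classes


class TestBinning:
    def test_six_bins_for_default_session(self):
        rec = TurnRecord("LRLR", np.array([1.0, 2, 3, 4]))
        df = bin_tetragrams(rec)
        assert len(df) == 6

    def test_all_turns_in_first_bin(self):
        rec = TurnRecord("LRLRLR", np.arange(6.0))
        df = bin_tetragrams(rec, 600, 3600)
        assert df.loc[0, "total"] == 3
        assert df.loc[0, "alternation_percent"] == pytest.approx(100.0)
        assert (df.loc[1:, "total"] == 0).all()
        assert df.loc[1:, "alternation_percent"].isna().all()

    def test_uniform_alternating_turns_every_bin_100(self, maze):
        times = np.linspace(1, 3599, 360)
        turns = ("LR" * 180)
        df = bin_tetragrams(TurnRecord(turns, times))
        assert (df["total"] > 0).all()
        assert np.allclose(df["alternation_percent"], 100.0)

    def test_assignment_by_fourth_turn_time(self):
        # fourth turn lands at 650 s -> bin 1 despite earlier turns in bin 0
        rec = TurnRecord("LRLR", np.array([10.0, 20, 30, 650]))
        df = bin_tetragrams(rec)
        assert df.loc[0, "total"] == 0 and df.loc[1, "total"] == 1

    def test_indivisible_bin_rejected(self):
        with pytest.raises(YMazeError):
            bin_tetragrams(TurnRecord("", np.empty(0)), 700, 3600)


class TestSpatialMetrics:
    def test_parked_fish(self, maze):
        p = np.asarray(maze.arms[0].polygon.representative_point().coords[0])
        tr = track_from_path([p] * 200, fps=FPS)
        m = spatial_metrics(tr, maze, (10, 10), FPS)
        assert m["heatmap"].max() == pytest.approx(1.0)
        assert m["velocity_median"] == pytest.approx(0.0)

    def test_heatmap_normalized(self, maze):
        tr = scripted_track(maze, random_turns(20, 0.5, seed=2))
        m = spatial_metrics(tr, maze, (20, 20), FPS)
        assert m["heatmap"].sum() == pytest.approx(1.0)

    def test_scripted_habituation_time(self, maze):
        inside = np.asarray(maze.arms[maze.habituation_arm]
                            .polygon.representative_point().coords[0])
        outside = np.asarray(maze.arms[1].polygon.representative_point().coords[0])
        n_in, n_out = int(30 * FPS), int(90 * FPS)
        tr = track_from_path([inside] * n_in + [outside] * n_out, fps=FPS)
        m = spatial_metrics(tr, maze, (10, 10), FPS)
        assert m["habituation_arm_seconds"] == pytest.approx(30.0)

    def test_empty_track_all_missing(self, maze):
        tr = track_from_path(np.empty((0, 2)))
        m = spatial_metrics(tr, maze)
        assert m["heatmap"] is None and m["habituation_arm_seconds"] is None


class TestChanceTests:
    def test_exactly_at_chance(self):
        df = chance_tests({0: [12.5] * 10})
        assert df.loc[0, "t"] == 0.0 and df.loc[0, "p"] == 1.0

    def test_degenerate_constant_100(self):
        df = chance_tests({0: [100.0] * 10})
        assert df.loc[0, "degenerate"]
        assert np.isinf(df.loc[0, "t"])

    def test_small_bin_skipped(self):
        df = chance_tests({0: [50.0], 1: [20.0, 30.0, 25.0]})
        assert np.isnan(df.loc[0, "p"]) and np.isfinite(df.loc[1, "p"])

    def test_fdr_column_adjusts_across_bins(self):
        rng = np.random.default_rng(3)
        bins = {b: list(12.5 + rng.normal(0, 5, 12)) for b in range(6)}
        df = chance_tests(bins)
        assert (df["p_fdr"].dropna() >= df["p"].dropna() - 1e-12).all()

    def test_type_i_error_controlled_under_fair_turns(self):
        """Monte-Carlo null: i.i.d. fair-turn fish tested against 12.5%
        rejects at alpha=0.05 about 5% of the time (200 replicates,
        60 fish x 100 turns)."""
        rng = np.random.default_rng(12345)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            # vectorized i.i.d. fair turns, alternation % per fish
            turns = rng.integers(0, 2, size=(60, 100))
            alt = np.empty(60)
            for i in range(60):
                s = turns[i]
                w = np.lib.stride_tricks.sliding_window_view(s, 4)
                is_alt = (np.abs(np.diff(w, axis=1)).sum(axis=1) == 3)
                alt[i] = 100.0 * is_alt.mean()
            df = chance_tests({0: list(alt)})
            if df.loc[0, "p"] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08


class TestEndToEndTurnRecovery:
    def test_scripted_turns_recovered_exactly(self, maze):
        for seed in range(5):
            turns = random_turns(40, 0.5, seed=seed)
            tr = scripted_track(maze, turns)
            entries, times = detect_entries(tr, maze, 5, FPS)
            assert turns_from_entries(entries, times).turns == turns
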