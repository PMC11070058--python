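import itertools
import random

import pytest

from sctrack.metrics import (
    Detection,
    DivisionEvent,
    cdf1,
    class_f1,
    divisions_from_forest,
    division_frame_tolerance,
    idf1,
    match_detections,
    match_frames,
    mota,
    tracks_from_forest,
)
from .conftest import (
    brute_force_idf1,
    brute_force_mota,
    make_tracks,
    square_instance,
)


class TestMatchDetections:
    def _det(self, x, y, size, iid, frame=0):
        return Detection(
            frame=frame, instance_id=iid,
            cell=square_instance(x, y, size, frame=frame, instance_id=iid),
        )

    def test_identical_all_matched(self):
        dets = [self._det(10, 10, 8, 1), self._det(40, 40, 8, 2)]
        pairs = match_detections(dets, dets)
        assert len(pairs) == 2

    def test_disjoint_none(self):
        a = [self._det(10, 10, 8, 1)]
        b = [self._det(100, 100, 8, 1)]
        assert match_detections(a, b) == []

    def test_threshold_and_one_to_one(self):
        gt = [self._det(10, 10, 10, 1), self._det(22, 10, 10, 2)]
        pred = [self._det(12, 10, 10, 1)]  # IoU 0.667 with gt1, 0 with gt2
        pairs = match_detections(gt, pred)
        assert len(pairs) == 1 and pairs[0][0].instance_id == 1

    def test_key_matcher(self):
        gt = [Detection(frame=0, instance_id=1), Detection(frame=0, instance_id=2)]
        pred = [Detection(frame=0, instance_id=2)]
        pairs = match_detections(gt, pred, matcher="key")
        assert len(pairs) == 1 and pairs[0][0].instance_id == 2


class TestIdf1:
    def test_perfect(self):
        tracks = make_tracks({1: {f: f * 10 + 1 for f in range(10)}})
        assert idf1(tracks, tracks, matcher="key") == 1.0

    def test_split_track_half(self):
        gt = make_tracks({1: {f: f for f in range(10)}})
        pred = make_tracks({
            7: {f: f for f in range(5)},
            8: {f: f for f in range(5, 10)},
        })
        assert idf1(gt, pred, matcher="key") == 0.5
        assert brute_force_idf1(gt, pred) == 0.5

    def test_empty_pred_zero(self):
        gt = make_tracks({1: {f: f for f in range(10)}})
        assert idf1(gt, {}, matcher="key") == 0.0

    def test_vacuous_perfect(self):
        assert idf1({}, {}, matcher="key") == 1.0

    def test_relabelling_invariance(self):
        gt = make_tracks({1: {0: 1, 1: 1}, 2: {0: 2, 1: 2}})
        pred = make_tracks({9: {0: 1, 1: 1}, 4: {0: 2, 1: 2}})
        assert idf1(gt, pred, matcher="key") == 1.0

    def test_brute_force_equivalence_random(self):
        from .conftest import random_track_instance

        rng = random.Random(13)
        for trial in range(30):
            gt, pred = random_track_instance(rng, max_tracks=4, max_frames=8)
            if not gt or not pred:
                continue
            got = idf1(gt, pred, matcher="key")
            want = brute_force_idf1(gt, pred)
            assert got == pytest.approx(want), (trial, gt, pred)


class TestMota:
    def test_perfect(self):
        tracks = make_tracks({1: {f: f for f in range(10)}})
        assert mota(tracks, tracks, matcher="key") == 1.0

    def test_formula_substitution(self):
        # 10 gt detections; 1 FN, 1 FP, 1 ID switch -> 1 - 3/10 = 0.7
        gt = make_tracks({1: {f: f for f in range(10)}})
        pred = make_tracks({
            7: {f: f for f in range(5)},
            8: {f: f for f in range(5, 9)},  # frame 9 missed (FN) + switch at 5
        })
        pred[8][9] = Detection(frame=9, instance_id=555)  # unmatched (FP)
        assert mota(gt, pred, matcher="key") == pytest.approx(0.7)
        assert brute_force_mota(gt, pred) == pytest.approx(0.7)

    def test_empty_pred(self):
        gt = make_tracks({1: {f: f for f in range(10)}})
        assert mota(gt, {}, matcher="key") == 0.0

    def test_empty_gt_undefined(self):
        assert mota({}, make_tracks({1: {0: 1}}), matcher="key") is None

    def test_id_relabelling_invariance(self):
        gt = make_tracks({1: {0: 1, 1: 1}})
        pred_a = make_tracks({5: {0: 1, 1: 1}})
        pred_b = make_tracks({99: {0: 1, 1: 1}})
        assert mota(gt, pred_a, matcher="key") == mota(gt, pred_b, matcher="key")

    def test_brute_force_equivalence_random(self):
        from .conftest import random_track_instance

        rng = random.Random(29)
        for _ in range(30):
            gt, pred = random_track_instance(rng, max_tracks=4, max_frames=8)
            got = mota(gt, pred, matcher="key")
            want = brute_force_mota(gt, pred)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


class TestCdf1:
    def _matching(self, pairs_by_frame):
        """pairs_by_frame: {frame: [(gt_tid, pred_tid)]} with dummy detections."""
        return {
            f: [
                (g, p, Detection(frame=f, instance_id=g), Detection(frame=f, instance_id=p))
                for g, p in pairs
            ]
            for f, pairs in pairs_by_frame.items()
        }

    def test_all_recovered(self):
        gt = [DivisionEvent(frame=5, mother=1, daughter_a=2, daughter_b=3)]
        pred = [DivisionEvent(frame=5, mother=11, daughter_a=12, daughter_b=13)]
        matching = self._matching({5: [(2, 12), (3, 13)]})
        assert cdf1(gt, pred, matching) == 1.0

    def test_hand_computed_arithmetic(self):
        # CDTP=2, CDFP=1, CDFN=1 -> 4/6
        gt = [
            DivisionEvent(frame=5, mother=1, daughter_a=2, daughter_b=3),
            DivisionEvent(frame=9, mother=4, daughter_a=5, daughter_b=6),
            DivisionEvent(frame=20, mother=7, daughter_a=8, daughter_b=9),
        ]
        pred = [
            DivisionEvent(frame=5, mother=11, daughter_a=12, daughter_b=13),
            DivisionEvent(frame=9, mother=14, daughter_a=15, daughter_b=16),
            DivisionEvent(frame=30, mother=17, daughter_a=18, daughter_b=19),
        ]
        matching = self._matching({
            5: [(2, 12), (3, 13)],
            9: [(5, 15), (6, 16)],
            30: [(8, 18), (9, 19)],  # daughters right but frame off by 10
        })
        assert cdf1(gt, pred, matching) == pytest.approx(4 / 6)

    def test_no_pred_divisions(self):
        gt = [DivisionEvent(frame=5, mother=1, daughter_a=2, daughter_b=3)]
        assert cdf1(gt, [], {}) == 0.0

    def test_no_divisions_undefined(self):
        assert cdf1([], [], {}) is None

    def test_swapped_daughters_not_matched(self):
        gt = [
            DivisionEvent(frame=5, mother=1, daughter_a=2, daughter_b=3),
            DivisionEvent(frame=5, mother=4, daughter_a=5, daughter_b=6),
        ]
        pred = [DivisionEvent(frame=5, mother=11, daughter_a=12, daughter_b=13)]
        # pred daughters land in different gt lineages
        matching = self._matching({5: [(2, 12), (5, 13)]})
        assert cdf1(gt, pred, matching) == 0.0


class TestDivisionFrameTolerance:
    def _setup(self, gt_frame, pred_frame):
        gt = [DivisionEvent(frame=gt_frame, mother=1, daughter_a=2, daughter_b=3)]
        pred = [DivisionEvent(frame=pred_frame, mother=11, daughter_a=12, daughter_b=13)]
        matching = {
            pred_frame: [
                (2, 12, Detection(frame=pred_frame, instance_id=1),
                 Detection(frame=pred_frame, instance_id=2)),
                (3, 13, Detection(frame=pred_frame, instance_id=3),
                 Detection(frame=pred_frame, instance_id=4)),
            ]
        }
        return gt, pred, matching

    def test_same_frame_tol_zero(self):
        gt, pred, matching = self._setup(5, 5)
        assert len(division_frame_tolerance(gt, pred, matching, tol=0)) == 1

    def test_off_by_one(self):
        gt, pred, matching = self._setup(5, 6)
        assert division_frame_tolerance(gt, pred, matching, tol=0) == []
        assert len(division_frame_tolerance(gt, pred, matching, tol=1)) == 1


class TestClassF1:
    def _tracks(self, labels, offset=0):
        return {
            1: {
                f: Detection(frame=f, instance_id=f, label=lbl)
                for f, lbl in enumerate(labels)
            }
        }

    def test_perfect(self):
        gt = self._tracks(["A", "B", "A", "C"])
        out = class_f1(gt, gt, matcher="key")
        assert out == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_tp8_fp2_fn2(self):
        gt = self._tracks(["A"] * 10 + ["B"] * 10)
        pred = self._tracks(["A"] * 8 + ["B"] * 2 + ["A"] * 2 + ["B"] * 8)
        out = class_f1(gt, pred, matcher="key")
        assert out["A"] == pytest.approx(0.8)

    def test_all_wrong(self):
        gt = self._tracks(["A", "A", "A"])
        pred = self._tracks(["B", "B", "B"])
        out = class_f1(gt, pred, matcher="key")
        assert out["A"] == 0.0 and out["B"] == 0.0


class TestForestMetrics:
    def test_perfect_forest_scores(self, small_movie):
        frames, truth, divisions = small_movie
        from sctrack.pipeline import run

        forest, _, _ = run(frames)
        gt_tracks = tracks_from_forest(truth)
        pred_tracks = tracks_from_forest(forest)
        assert idf1(gt_tracks, pred_tracks) == 1.0
        assert mota(gt_tracks, pred_tracks) == 1.0
        matching = match_frames(gt_tracks, pred_tracks)
        assert cdf1(divisions, divisions_from_forest(forest), matching) == 1.0

    def test_cdf1_degrades_with_corruption(self, small_movie):
        frames, truth, divisions = small_movie
        from sctrack.pipeline import run

        forest, _, _ = run(frames)
        pred_divs = divisions_from_forest(forest)
        gt_tracks = tracks_from_forest(truth)
        pred_tracks = tracks_from_forest(forest)
        matching = match_frames(gt_tracks, pred_tracks)
        base = cdf1(divisions, pred_divs, matching)
        corrupted = [
            DivisionEvent(frame=d.frame, mother=d.mother,
                          daughter_a=d.daughter_a, daughter_b=99999)
            for d in pred_divs
        ]
        assert cdf1(divisions, corrupted, matching) <= base
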