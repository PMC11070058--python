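"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sctrack.config import TrackerConfig
from sctrack.features import extract_instances, instance_from_polygon
from sctrack.metrics import Detection
from sctrack.synthetic import SimulationConfig, simulate_timelapse


def square_instance(x0, y0, size, frame=0, instance_id=1, label=3, **kwargs):
    """A size x size square of pixels built through mask extraction."""
    mask = np.zeros((y0 + size + 5, x0 + size + 5), dtype=np.uint8)
    mask[y0 : y0 + size, x0 : x0 + size] = label
    fs = extract_instances(mask, frame=frame, **kwargs)
    inst = fs.instances[0]
    object.__setattr__(inst, "instance_id", instance_id)
    object.__setattr__(inst, "frame", frame)
    return inst


def poly_instance(xs, ys, frame=0, instance_id=1, class_label=None):
    return instance_from_polygon(xs, ys, frame=frame, instance_id=instance_id,
                                 class_label=class_label)


#: an asymmetric hexagon: all seven Hu invariants are comfortably nonzero
IRREGULAR_POLY = np.array(
    [[0.0, 0.0], [5.0, 1.0], [7.0, 4.0], [4.0, 8.0], [1.0, 6.0], [0.5, 2.0]]
)


@pytest.fixture(scope="session")
def default_config():
    return TrackerConfig()


@pytest.fixture(scope="session")
def small_movie():
    """10 cells x 40 frames x 2 divisions with class labels, plus truth."""
    cfg = SimulationConfig(n_cells=10, n_frames=40, n_divisions=2,
                           with_classes=True, seed=11)
    return simulate_timelapse(cfg)


@pytest.fixture(scope="session")
def plain_movie():
    """5 cells x 25 frames, no divisions, no classes."""
    cfg = SimulationConfig(n_cells=5, n_frames=25, with_classes=False, seed=4)
    return simulate_timelapse(cfg)


# -- independent metric oracles (brute force; used only to check metrics) ---


def make_tracks(spec):
    """Build a tracks dict from {tid: {frame: iid}} using key identity."""
    return {
        tid: {f: Detection(frame=f, instance_id=iid) for f, iid in dets.items()}
        for tid, dets in spec.items()
    }


def random_track_instance(rng, max_tracks=5, max_frames=10):
    """Random well-formed gt/pred track pair: detection keys are unique
    within every frame on each side (as real per-frame instance ids are)."""
    n_frames = rng.randint(1, max_frames)
    n_gt = rng.randint(1, max_tracks)
    n_pred = rng.randint(1, max_tracks)
    gt = {}
    for t in range(n_gt):
        dets = {
            f: Detection(frame=f, instance_id=t + 1)
            for f in range(n_frames) if rng.random() < 0.8
        }
        if dets:
            gt[t] = dets
    pred = {}
    fp_counter = 1000
    for t in range(n_pred):
        dets = {}
        for f in range(n_frames):
            if rng.random() >= 0.8:
                continue
            taken = {d[f].instance_id for d in pred.values() if f in d}
            if rng.random() < 0.8:
                candidates = [
                    g + 1 for g in range(n_gt)
                    if g in gt and f in gt[g] and g + 1 not in taken
                ]
                if candidates:
                    dets[f] = Detection(frame=f, instance_id=rng.choice(candidates))
                    continue
            fp_counter += 1
            dets[f] = Detection(frame=f, instance_id=fp_counter)
        if dets:
            pred[t + 50] = dets
    return gt, pred


def brute_force_idf1(gt_tracks, pred_tracks):
    """IDF1 by exhaustive enumeration of injective pred->gt ID assignments.

    Detections correspond when they share (frame, instance_id) keys; a
    matched frame counts toward IDTP only for the assigned track pair.
    """
    n_gt = sum(len(d) for d in gt_tracks.values())
    n_pred = sum(len(d) for d in pred_tracks.values())
    if n_gt == 0 and n_pred == 0:
        return 1.0
    if n_gt == 0 or n_pred == 0:
        return 0.0
    gt_ids = sorted(gt_tracks)
    pred_ids = sorted(pred_tracks)

    def overlap(g, p):
        gd = gt_tracks[g]
        pd = pred_tracks[p]
        return sum(
            1 for f, det in gd.items() if f in pd and pd[f].key == det.key
        )

    best = 0
    k = min(len(gt_ids), len(pred_ids))
    for size in range(k + 1):
        for gs in itertools.combinations(gt_ids, size):
            for ps in itertools.permutations(pred_ids, size):
                best = max(best, sum(overlap(g, p) for g, p in zip(gs, ps)))
    idtp = best
    return 2 * idtp / (2 * idtp + (n_pred - idtp) + (n_gt - idtp))


def brute_force_mota(gt_tracks, pred_tracks):
    """Direct per-frame MOTA recomputation with key-identity matching."""
    frames = sorted(
        {f for d in gt_tracks.values() for f in d}
        | {f for d in pred_tracks.values() for f in d}
    )
    gt_total = sum(len(d) for d in gt_tracks.values())
    if gt_total == 0:
        return None
    fn = fp = idsw = 0
    last = {}
    for f in frames:
        gt_here = {tid: d[f] for tid, d in gt_tracks.items() if f in d}
        pred_here = {tid: d[f] for tid, d in pred_tracks.items() if f in d}
        pred_by_key = {det.key: tid for tid, det in pred_here.items()}
        matched_pred = set()
        for g_tid in sorted(gt_here):
            key = gt_here[g_tid].key
            if key in pred_by_key:
                p_tid = pred_by_key[key]
                matched_pred.add(p_tid)
                if g_tid in last and last[g_tid] != p_tid:
                    idsw += 1
                last[g_tid] = p_tid
            else:
                fn += 1
        fp += len(pred_here) - len(matched_pred)
    return 1.0 - (fn + fp + idsw) / gt_total
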