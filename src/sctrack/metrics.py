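"""Tracking evaluation: detection matching, IDF1, MOTA, CDF1, per-class F1.

Tracks are represented as ``{track_id: {frame: Detection}}``.  Detections are
matched per frame either by rasterized IoU (greedy, descending, threshold
``iou_min``) or — for geometry-free lineage tables — by their
``(frame, instance_id)`` key.  Gap-filled nodes are imputations, not
detections, and must be excluded before scoring (see
:func:`tracks_from_forest`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .features import CellInstance, mask_iou
from .tracktree import TrackForest

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "MOTCounts",
    "DivisionEvent",
    "tracks_from_forest",
    "divisions_from_forest",
    "match_detections",
    "match_frames",
    "idf1",
    "mota",
    "cdf1",
    "class_f1",
    "division_frame_tolerance",
]


@dataclass(frozen=True)
class Detection:
    """One detection of one track in one frame."""

    frame: int
    instance_id: int
    cell: Optional[CellInstance] = None
    label: Optional[str] = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.frame, self.instance_id)


@dataclass
class MOTCounts:
    """Identity- and event-level error counts."""

    IDTP: int = 0
    IDFP: int = 0
    IDFN: int = 0
    FP: int = 0
    FN: int = 0
    IDsw: int = 0
    GT: int = 0


@dataclass(frozen=True)
class DivisionEvent:
    """A division: mother track splits into two daughter tracks at ``frame``."""

    frame: int
    mother: int
    daughter_a: int
    daughter_b: int

    @property
    def daughters(self) -> frozenset:
        return frozenset((self.daughter_a, self.daughter_b))


Tracks = dict  # {track_id: {frame: Detection}}


def tracks_from_forest(
    forest: TrackForest,
    include_gap_fill: bool = False,
    use_smoothed: bool = True,
) -> Tracks:
    """Per-branch tracks from a forest; branch ids are the track identities."""
    tracks: Tracks = {}
    for branch in forest.iter_branches():
        dets = {}
        for node in branch.nodes:
            if node.is_gap_fill and not include_gap_fill:
                continue
            label = node.smoothed_class if (use_smoothed and node.smoothed_class is not None) else node.raw_class
            dets[node.frame] = Detection(
                frame=node.frame,
                instance_id=node.cell.instance_id,
                cell=node.cell,
                label=label,
            )
        if dets:
            tracks[branch.branch_id] = dets
    return tracks


def divisions_from_forest(forest: TrackForest) -> list[DivisionEvent]:
    """All division events (closed branches with two children)."""
    events = []
    for branch in forest.iter_branches():
        if len(branch.child_branch_ids) == 2:
            tree = forest.trees[branch.tree_id]
            a, b = sorted(branch.child_branch_ids)
            frame = tree.branches[a].start_frame
            events.append(DivisionEvent(frame=frame, mother=branch.branch_id,
                                        daughter_a=a, daughter_b=b))
    events.sort(key=lambda e: (e.frame, e.mother))
    return events


def match_detections(
    gt_dets: Sequence[Detection],
    pred_dets: Sequence[Detection],
    iou_min: float = 0.5,
    matcher: str = "iou",
) -> list[tuple[Detection, Detection]]:
    """Greedy one-to-one matching of one frame's detections.

    ``matcher='iou'`` pairs by descending mask IoU (pairs below ``iou_min``
    stay unmatched, ties broken by ids); ``matcher='key'`` pairs detections
    sharing the same ``(frame, instance_id)`` key.
    """
    if matcher == "key":
        by_key = {d.key: d for d in pred_dets}
        return [(g, by_key[g.key]) for g in gt_dets if g.key in by_key]
    if matcher != "iou":
        raise ValueError(f"unknown matcher {matcher!r}")
    pairs = []
    for g in gt_dets:
        for p in pred_dets:
            iou = mask_iou(g.cell, p.cell)
            if iou >= iou_min:
                pairs.append((iou, g.instance_id, p.instance_id, g, p))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g: set[int] = set()
    used_p: set[int] = set()
    out = []
    for iou, gid, pid, g, p in pairs:
        if gid in used_g or pid in used_p:
            continue
        used_g.add(gid)
        used_p.add(pid)
        out.append((g, p))
    return out


def _frames_of(tracks: Tracks) -> list[int]:
    return sorted({f for dets in tracks.values() for f in dets})


def match_frames(
    gt_tracks: Tracks,
    pred_tracks: Tracks,
    iou_min: float = 0.5,
    matcher: str = "iou",
) -> dict[int, list[tuple[int, int, Detection, Detection]]]:
    """Per-frame correspondences ``frame -> [(gt_tid, pred_tid, gt_det, pred_det)]``."""
    gt_owner = {d.key: tid for tid, dets in gt_tracks.items() for d in dets.values()}
    pred_owner = {d.key: tid for tid, dets in pred_tracks.items() for d in dets.values()}
    frames = sorted(set(_frames_of(gt_tracks)) | set(_frames_of(pred_tracks)))
    out: dict[int, list] = {}
    for f in frames:
        gt_dets = sorted(
            (dets[f] for dets in gt_tracks.values() if f in dets),
            key=lambda d: d.instance_id,
        )
        pred_dets = sorted(
            (dets[f] for dets in pred_tracks.values() if f in dets),
            key=lambda d: d.instance_id,
        )
        out[f] = [
            (gt_owner[g.key], pred_owner[p.key], g, p)
            for g, p in match_detections(gt_dets, pred_dets, iou_min, matcher)
        ]
    return out


def _count_dets(tracks: Tracks) -> int:
    return sum(len(dets) for dets in tracks.values())


def idf1(
    gt_tracks: Tracks,
    pred_tracks: Tracks,
    iou_min: float = 0.5,
    matcher: str = "iou",
) -> float:
    """Identity F1 under the optimal global gt/pred track-identity assignment.

    Per-frame detection correspondences are accumulated into a match-count
    matrix; the bijective assignment maximizing the total (IDTP) is solved
    exactly, and ``IDF1 = 2*IDTP / (2*IDTP + IDFP + IDFN)``.
    """
    n_gt = _count_dets(gt_tracks)
    n_pred = _count_dets(pred_tracks)
    if n_gt == 0 and n_pred == 0:
        return 1.0
    if n_gt == 0 or n_pred == 0:
        return 0.0
    gt_ids = sorted(gt_tracks)
    pred_ids = sorted(pred_tracks)
    counts = np.zeros((len(gt_ids), len(pred_ids)), dtype=float)
    gi = {tid: i for i, tid in enumerate(gt_ids)}
    pi = {tid: i for i, tid in enumerate(pred_ids)}
    for pairs in match_frames(gt_tracks, pred_tracks, iou_min, matcher).values():
        for g_tid, p_tid, _, _ in pairs:
            counts[gi[g_tid], pi[p_tid]] += 1
    rows, cols = linear_sum_assignment(counts, maximize=True)
    idtp = int(counts[rows, cols].sum())
    idfp = n_pred - idtp
    idfn = n_gt - idtp
    return 2 * idtp / (2 * idtp + idfp + idfn)


def mota(
    gt_tracks: Tracks,
    pred_tracks: Tracks,
    iou_min: float = 0.5,
    matcher: str = "iou",
    return_counts: bool = False,
):
    """``MOTA = 1 - sum(FN + FP + IDsw) / sum(GT)``; None when GT is empty.

    FN/FP come from per-frame detection matching; an identity switch is
    counted whenever a ground-truth track's matched predicted identity
    differs from the identity it was last matched to.
    """
    counts = MOTCounts()
    counts.GT = _count_dets(gt_tracks)
    if counts.GT == 0:
        return (None, counts) if return_counts else None
    per_frame = match_frames(gt_tracks, pred_tracks, iou_min, matcher)
    last_match: dict[int, int] = {}
    for f in sorted(per_frame):
        pairs = per_frame[f]
        n_gt = sum(1 for dets in gt_tracks.values() if f in dets)
        n_pred = sum(1 for dets in pred_tracks.values() if f in dets)
        counts.FN += n_gt - len(pairs)
        counts.FP += n_pred - len(pairs)
        for g_tid, p_tid, _, _ in pairs:
            if g_tid in last_match and last_match[g_tid] != p_tid:
                counts.IDsw += 1
            last_match[g_tid] = p_tid
    value = 1.0 - (counts.FN + counts.FP + counts.IDsw) / counts.GT
    return (value, counts) if return_counts else value


def division_frame_tolerance(
    gt_divisions: Sequence[DivisionEvent],
    pred_divisions: Sequence[DivisionEvent],
    matching: dict[int, list[tuple[int, int, Detection, Detection]]],
    tol: int = 1,
) -> list[tuple[DivisionEvent, DivisionEvent]]:
    """Pairs of gt/pred divisions whose frames differ by <= ``tol`` and whose
    daughter detections correspond across gt and pred."""
    # pred track -> gt track correspondence per frame
    pred_to_gt: dict[int, dict[int, int]] = {}
    for f, pairs in matching.items():
        pred_to_gt[f] = {p_tid: g_tid for g_tid, p_tid, _, _ in pairs}

    matched = []
    used_gt: set[int] = set()
    for pred_div in sorted(pred_divisions, key=lambda e: (e.frame, e.mother)):
        frame_map = pred_to_gt.get(pred_div.frame, {})
        gt_daughters = {
            frame_map.get(pred_div.daughter_a),
            frame_map.get(pred_div.daughter_b),
        }
        if None in gt_daughters or len(gt_daughters) != 2:
            continue
        best = None
        for i, gt_div in enumerate(gt_divisions):
            if i in used_gt:
                continue
            if abs(gt_div.frame - pred_div.frame) > tol:
                continue
            if gt_div.daughters != frozenset(gt_daughters):
                continue
            key = (abs(gt_div.frame - pred_div.frame), gt_div.frame)
            if best is None or key < best[0]:
                best = (key, i, gt_div)
        if best is not None:
            used_gt.add(best[1])
            matched.append((best[2], pred_div))
    return matched


def cdf1(
    gt_divisions: Sequence[DivisionEvent],
    pred_divisions: Sequence[DivisionEvent],
    matching: dict[int, list[tuple[int, int, Detection, Detection]]],
    tol: int = 1,
) -> Optional[float]:
    """``CDF1 = 2*CDTP / (2*CDTP + CDFP + CDFN)``; None when no divisions exist.

    A predicted division is a true positive iff both daughter detections
    correspond to the two daughters of a single ground-truth division (within
    ``tol`` frames of division timing).
    """
    if not gt_divisions and not pred_divisions:
        return None
    cdtp = len(division_frame_tolerance(gt_divisions, pred_divisions, matching, tol))
    cdfp = len(pred_divisions) - cdtp
    cdfn = len(gt_divisions) - cdtp
    return 2 * cdtp / (2 * cdtp + cdfp + cdfn)


def class_f1(
    gt_tracks: Tracks,
    pred_tracks: Tracks,
    iou_min: float = 0.5,
    matcher: str = "iou",
) -> dict[str, Optional[float]]:
    """One-vs-rest per-class F1 over label pairs aligned by detection matching.

    Classes absent from both sides map to None (undefined).
    """
    pairs: list[tuple[Optional[str], Optional[str]]] = []
    for frame_pairs in match_frames(gt_tracks, pred_tracks, iou_min, matcher).values():
        for _, _, g, p in frame_pairs:
            pairs.append((g.label, p.label))
    classes = sorted(
        {g for g, _ in pairs if g is not None} | {p for _, p in pairs if p is not None}
    )
    out: dict[str, Optional[float]] = {}
    for cls in classes:
        tp = sum(1 for g, p in pairs if g == cls and p == cls)
        fp = sum(1 for g, p in pairs if g != cls and p == cls)
        fn = sum(1 for g, p in pairs if g == cls and p != cls)
        if tp + fp + fn == 0:
            out[cls] = None
        else:
            out[cls] = 2 * tp / (2 * tp + fp + fn)
    return out
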