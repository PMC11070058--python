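"""End-to-end orchestration: track -> refine -> class smoothing -> export,
and the evaluation entry point (IDF1 / MOTA / CDF1 / per-class F1)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import metrics as _metrics
from .config import TrackerConfig
from .errors import FormatError
from .features import FrameSegmentation
from .io_formats import read_lineage_csv
from .refiner import refine
from .tcs import apply_tcs
from .tracker import track
from .tracktree import LineageRecord, TrackForest, export_lineage

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run", "evaluate"]

UNDEFINED = "–"  # rendering of undefined metric values


@dataclass
class RunReport:
    """Per-stage bookkeeping of one tracking run."""

    n_frames: int = 0
    instances_in: int = 0
    linked_unique: int = 0
    linked_by_similarity: int = 0
    linked_expanded: int = 0
    division_daughter: int = 0
    cache_relinked: int = 0
    new_tree: int = 0
    divisions: int = 0
    pruned_singletons: int = 0
    fragments_linked: int = 0
    trees_discarded: int = 0
    gaps_filled: int = 0
    labels_corrected: int = 0
    n_trees: int = 0
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def run(
    frames: Sequence[FrameSegmentation],
    config: Optional[TrackerConfig] = None,
) -> tuple[TrackForest, list[LineageRecord], RunReport]:
    """Full pipeline on a frame sequence; deterministic given config."""
    config = config or TrackerConfig()
    if not frames:
        raise FormatError("no frames to track")
    report = RunReport(
        n_frames=len(frames),
        instances_in=sum(len(fs.instances) for fs in frames),
        config=config.to_dict(),
    )
    forest = track(frames, config)
    for decision in forest.decisions:
        setattr(report, decision.outcome, getattr(report, decision.outcome) + 1)

    final_frame = max(fs.frame for fs in frames)
    forest, counts = refine(forest, config, final_frame=final_frame)
    for key, value in counts.items():
        setattr(report, key, value)

    if forest.has_class_labels():
        apply_tcs(forest, config)
        report.labels_corrected = sum(
            1 for n in forest.iter_nodes()
            if n.smoothed_class is not None and n.smoothed_class != n.raw_class
        )
    report.divisions = len(_metrics.divisions_from_forest(forest))
    report.n_trees = len(forest.trees)
    records = export_lineage(forest)
    logger.info(
        "tracked %d instances over %d frames into %d trees (%d divisions)",
        report.instances_in, report.n_frames, report.n_trees, report.divisions,
    )
    return forest, records, report


def _tracks_from_records(records: Sequence[LineageRecord], use_smoothed: bool):
    tracks: dict = {}
    for r in records:
        if r.is_gap_fill:
            continue
        label = r.smoothed_class if (use_smoothed and r.smoothed_class) else r.raw_class
        det = _metrics.Detection(frame=r.frame, instance_id=r.instance_id, label=label)
        tracks.setdefault(r.branch_id, {})[r.frame] = det
    return tracks


def _divisions_from_records(records: Sequence[LineageRecord]):
    children: dict[int, list] = {}
    starts: dict[int, int] = {}
    for r in records:
        if r.branch_id not in starts or r.frame < starts[r.branch_id]:
            starts[r.branch_id] = r.frame
    seen = set()
    for r in records:
        if r.parent_branch_id is not None and r.branch_id not in seen:
            children.setdefault(r.parent_branch_id, []).append(r.branch_id)
            seen.add(r.branch_id)
    events = []
    for mother, kids in children.items():
        kids = sorted(set(kids))
        if len(kids) == 2:
            frame = min(starts[k] for k in kids)
            events.append(
                _metrics.DivisionEvent(frame=frame, mother=mother,
                                       daughter_a=kids[0], daughter_b=kids[1])
            )
    events.sort(key=lambda e: (e.frame, e.mother))
    return events


Source = Union[TrackForest, Sequence[LineageRecord], str, Path]


def _load_source(source: Source, use_smoothed: bool):
    """Returns (tracks, divisions, has_geometry)."""
    if isinstance(source, TrackForest):
        return (
            _metrics.tracks_from_forest(source, use_smoothed=use_smoothed),
            _metrics.divisions_from_forest(source),
            True,
        )
    if isinstance(source, (str, Path)):
        source = read_lineage_csv(source)
    records = list(source)
    return (
        _tracks_from_records(records, use_smoothed),
        _divisions_from_records(records),
        False,
    )


def evaluate(
    gt: Source,
    pred: Source,
    iou_min: float = 0.5,
    division_tolerance: int = 1,
    use_smoothed: bool = True,
    matcher: Optional[str] = None,
) -> dict:
    """Score a prediction against ground truth.

    Both sides may be forests, lineage-record lists or lineage CSV paths.
    Detection matching uses rasterized IoU when both sides carry geometry,
    otherwise the shared ``(frame, instance_id)`` keys.  Undefined values
    (e.g. CDF1 without any divisions) are reported as None and rendered
    as "–".
    """
    gt_tracks, gt_divs, gt_geom = _load_source(gt, use_smoothed=False)
    pred_tracks, pred_divs, pred_geom = _load_source(pred, use_smoothed)
    if matcher is None:
        matcher = "iou" if (gt_geom and pred_geom) else "key"

    def frame_range(tracks):
        frames = [f for dets in tracks.values() for f in dets]
        return (min(frames), max(frames)) if frames else None

    gr, pr = frame_range(gt_tracks), frame_range(pred_tracks)
    if gr and pr and (pr[0] > gr[1] or gr[0] > pr[1]):
        raise FormatError(f"disjoint frame ranges: gt {gr} vs pred {pr}")

    matching = _metrics.match_frames(gt_tracks, pred_tracks, iou_min, matcher)
    result = {
        "idf1": _metrics.idf1(gt_tracks, pred_tracks, iou_min, matcher),
        "mota": _metrics.mota(gt_tracks, pred_tracks, iou_min, matcher),
        "cdf1": _metrics.cdf1(gt_divs, pred_divs, matching, division_tolerance),
        "class_f1": _metrics.class_f1(gt_tracks, pred_tracks, iou_min, matcher),
    }
    return result


def render_value(value) -> str:
    return UNDEFINED if value is None else f"{value:.4f}"
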