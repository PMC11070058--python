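"""Class smoothing along lineage branches (forward-window majority rule).

The first node's raw class becomes the running default.  At the first node
whose raw class differs, the labels of the next ``window`` nodes (excluding
the trigger) are counted; if the fraction matching the trigger's class
strictly exceeds ``threshold`` the default switches from the trigger onward,
otherwise the trigger is rewritten to the default.  The window shrinks near
the branch end; with fewer than ``min_window`` nodes remaining no switch is
allowed.  Each branch is smoothed independently and smoothing never crosses
a division.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .config import TrackerConfig
from .tracktree import TrackForest

logger = logging.getLogger(__name__)

__all__ = ["smooth_branch", "apply_tcs"]


def smooth_branch(
    classes: Sequence[Optional[str]],
    window: int = 9,
    threshold: float = 0.60,
    min_window: int = 3,
    per_class_thresholds: Optional[dict] = None,
) -> list[Optional[str]]:
    """Smooth one branch's per-frame raw labels; returns a new list."""
    n = len(classes)
    if n == 0:
        return []
    out: list[Optional[str]] = list(classes)
    default = classes[0]
    for i in range(1, n):
        label = classes[i]
        if label == default:
            continue
        remaining = n - 1 - i
        eff = min(window, remaining)
        thr = threshold
        if per_class_thresholds and label in per_class_thresholds:
            thr = per_class_thresholds[label]
        if eff >= min_window:
            count = sum(1 for c in classes[i + 1 : i + 1 + eff] if c == label)
            if count / eff > thr:
                default = label
                continue
        out[i] = default
    return out


def apply_tcs(forest: TrackForest, config: Optional[TrackerConfig] = None) -> TrackForest:
    """Set ``smoothed_class`` on every node, branch by branch.

    Daughter branches start fresh with their own first-node default.  A
    forest without class labels is returned unchanged (with a warning).
    """
    config = config or TrackerConfig()
    if not forest.has_class_labels():
        logger.warning("no class labels present; TCS is a no-op")
        return forest
    n_corrected = 0
    for branch in forest.iter_branches():
        raw = [node.raw_class for node in branch.nodes]
        smoothed = smooth_branch(
            raw,
            window=config.tcs_window,
            threshold=config.tcs_threshold,
            min_window=config.tcs_min_window,
            per_class_thresholds=config.per_class_tcs_thresholds,
        )
        for node, label in zip(branch.nodes, smoothed):
            node.smoothed_class = label
            if label != node.raw_class:
                n_corrected += 1
    logger.info("TCS corrected %d labels", n_corrected)
    return forest
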