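"""Post-tracking repair: prune singletons, link fragments, discard short
trees, fill gaps.  Operates in place on a :class:`TrackForest` and always in
that order (fragment linking must precede the short-track discard so that two
short fragments that join into a long track survive)."""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .config import TrackerConfig
from .errors import StateError
from .features import CellInstance, expand_bbox
from .similarity import similarity_index
from .tracktree import Branch, TrackForest, TrackNode, TrackTree

logger = logging.getLogger(__name__)

__all__ = [
    "prune_singletons",
    "link_fragments",
    "discard_short_trees",
    "fill_gaps",
    "refine",
]


def prune_singletons(forest: TrackForest) -> tuple[TrackForest, list[CellInstance]]:
    """Drop trees with a single node; these are assumed false-positive detections."""
    pruned: list[CellInstance] = []
    for tid in sorted(forest.trees):
        tree = forest.trees[tid]
        if tree.n_nodes() == 1:
            pruned.append(next(tree.iter_nodes()).cell)
            forest.remove_tree(tid)
    if pruned:
        logger.info("pruned %d singleton trees", len(pruned))
    return forest, pruned


def _ending_leaf(tree: TrackTree) -> Branch:
    # terminal end of the tree: the leaf whose tip frame is latest
    leaves = tree.leaves()
    leaves.sort(key=lambda b: (-b.end_frame, b.branch_id))
    return leaves[0]


def link_fragments(forest: TrackForest, config: Optional[TrackerConfig] = None) -> TrackForest:
    """Join tree fragments split by short detection gaps.

    Tree B (starting at frame ``t_s``) is appended to tree A (ending at
    ``t_e``) when ``0 < t_s - t_e <= fragment_link_gap`` and A's last centroid
    lies inside the expanded bounding box of B's first instance.  Competing
    predecessors are resolved by the similarity of the terminal instances;
    fragments are processed in ascending start frame.
    """
    config = config or TrackerConfig()
    merged = True
    while merged:
        merged = False
        candidates = sorted(
            forest.trees.values(), key=lambda t: (t.start_frame(), t.tree_id)
        )
        for tree_b in candidates:
            root = tree_b.branches[tree_b.root_branch_id]
            first = root.nodes[0].cell
            t_s = root.start_frame
            box = expand_bbox(first.bbox, config.alpha)
            best = None
            for tree_a in forest.trees.values():
                if tree_a.tree_id == tree_b.tree_id:
                    continue
                end_branch = _ending_leaf(tree_a)
                t_e = end_branch.end_frame
                if not (0 < t_s - t_e <= config.fragment_link_gap):
                    continue
                last = end_branch.tip.cell
                if not box.contains(*last.centroid):
                    continue
                sim = similarity_index(last, first, config.weights)
                key = (-sim.total, tree_a.tree_id)
                if best is None or key < best[0]:
                    best = (key, tree_a, end_branch)
            if best is None:
                continue
            _, tree_a, end_branch = best
            _graft(forest, tree_a, end_branch, tree_b)
            logger.info(
                "linked fragment tree %d (start %d) onto tree %d (end %d)",
                tree_b.tree_id, t_s, tree_a.tree_id, end_branch.end_frame,
            )
            merged = True
            break  # re-scan with fresh tree ends
    return forest


def _graft(forest: TrackForest, tree_a: TrackTree, end_branch: Branch, tree_b: TrackTree) -> None:
    """Append tree B's root branch to A's ending branch and adopt B's subtrees."""
    root_b = tree_b.branches[tree_b.root_branch_id]
    for node in root_b.nodes:
        if node.frame <= end_branch.end_frame:
            raise StateError("fragment linking would regress frames")
        node.branch_id = end_branch.branch_id
        end_branch.nodes.append(node)
    end_branch.closed = root_b.closed
    end_branch.child_branch_ids.extend(root_b.child_branch_ids)
    for bid, branch in tree_b.branches.items():
        if bid == root_b.branch_id:
            continue
        if branch.parent_branch_id == root_b.branch_id:
            branch.parent_branch_id = end_branch.branch_id
        tree_a.add_branch(branch)
    forest.remove_tree(tree_b.tree_id)


def discard_short_trees(
    forest: TrackForest,
    min_track_span: int = 10,
    final_frame: Optional[int] = None,
) -> tuple[TrackForest, list[TrackTree]]:
    """Remove trees spanning fewer than ``min_track_span`` frames.

    Exemptions: trees still open at the movie's final frame, and trees rooted
    at frame 0 of a movie shorter than ``min_track_span`` frames (otherwise a
    short movie would lose every cell).
    """
    if final_frame is None:
        final_frame = max(
            (t.end_frame() for t in forest.trees.values()), default=0
        )
    movie_too_short = final_frame + 1 < min_track_span
    discarded = []
    for tid in sorted(forest.trees):
        tree = forest.trees[tid]
        if tree.span() >= min_track_span:
            continue
        if tree.end_frame() >= final_frame:
            continue  # still open at the end of the movie
        if movie_too_short and tree.start_frame() == 0:
            continue
        discarded.append(forest.remove_tree(tid))
    if discarded:
        logger.info("discarded %d short trees (span < %d)", len(discarded), min_track_span)
    return forest, discarded


def fill_gaps(forest: TrackForest) -> tuple[TrackForest, int]:
    """Fill missing frames inside every branch with copies of the preceding node.

    Gap-fill nodes copy the geometry and raw class of the nearest preceding
    real node and are flagged ``is_gap_fill``; no real node is touched.
    """
    n_filled = 0
    for branch in forest.iter_branches():
        filled: list[TrackNode] = []
        prev: Optional[TrackNode] = None
        for node in branch.nodes:
            if prev is not None:
                for f in range(prev.frame + 1, node.frame):
                    filler = TrackNode(
                        cell=prev.cell.with_frame(f),
                        branch_id=branch.branch_id,
                        is_gap_fill=True,
                        raw_class=prev.raw_class,
                    )
                    filled.append(filler)
                    n_filled += 1
            filled.append(node)
            prev = node
        branch.nodes = filled
    if n_filled:
        logger.info("filled %d gap frames", n_filled)
    return forest, n_filled


def refine(
    forest: TrackForest,
    config: Optional[TrackerConfig] = None,
    final_frame: Optional[int] = None,
) -> tuple[TrackForest, dict]:
    """Run all four repair steps in order; returns the forest and stage counts."""
    config = config or TrackerConfig()
    forest, pruned = prune_singletons(forest)
    n_trees_before = len(forest.trees)
    link_fragments(forest, config)
    n_linked = n_trees_before - len(forest.trees)
    forest, discarded = discard_short_trees(forest, config.min_track_span, final_frame)
    forest, n_filled = fill_gaps(forest)
    _assert_contiguous(forest)
    counts = {
        "pruned_singletons": len(pruned),
        "fragments_linked": n_linked,
        "trees_discarded": len(discarded),
        "gaps_filled": n_filled,
    }
    return forest, counts


def _assert_contiguous(forest: TrackForest) -> None:
    for branch in forest.iter_branches():
        frames = [n.frame for n in branch.nodes]
        for a, b in zip(frames, frames[1:]):
            if b != a + 1:
                raise StateError(
                    f"branch {branch.branch_id} not frame-contiguous after refine"
                )
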