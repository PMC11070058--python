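"""Per-frame hierarchical linking cascade.

Each frame is resolved in tiers of decreasing confidence:

1. unique mask-overlap links,
2. similarity resolution of contested overlap groups,
3. expanded-bounding-box search for orphans against unmatched tips,
4. division detection (mother in the previous frame, biological rules),
5. cache matching against branches that ended within the last few frames,
6. new-tree initialization.

Every instance receives exactly one :class:`LinkDecision`; all tie-breaks
are total orders so runs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import TrackerConfig
from .features import CellInstance, FrameSegmentation, expand_bbox, mask_iou
from .similarity import similarity_index
from .tracktree import Branch, TrackForest

logger = logging.getLogger(__name__)

__all__ = [
    "LinkDecision",
    "link_by_overlap",
    "resolve_contested",
    "expanded_search_candidates",
    "detect_division",
    "cache_match",
    "track",
]

M_PHASE_LABEL = "M"


@dataclass(frozen=True)
class LinkDecision:
    """Audit record of how one instance was assigned."""

    frame: int
    instance_id: int
    outcome: str  # linked_unique | linked_by_similarity | linked_expanded |
    #               division_daughter | cache_relinked | new_tree
    branch_id: Optional[int] = None
    similarity: Optional[float] = None


def link_by_overlap(
    prev_tips: Sequence[Branch], cur: FrameSegmentation
) -> tuple[list[tuple[Branch, CellInstance]], list[tuple[list[Branch], list[CellInstance]]], list[CellInstance]]:
    """Partition current instances by mask overlap against previous-frame tips.

    Returns ``(unique_links, contested_groups, orphans)``:  instances with
    exactly one overlapping tip that overlaps nothing else are unique links;
    connected components of the overlap graph with multiplicity on either
    side form contested groups; instances with no overlap are orphans.
    """
    overlaps: dict[int, list[int]] = {}  # instance idx -> tip idxs
    tip_hits: dict[int, list[int]] = {i: [] for i in range(len(prev_tips))}
    for j, inst in enumerate(cur.instances):
        hits = []
        for i, branch in enumerate(prev_tips):
            tip_cell = branch.tip.cell
            if tip_cell.bbox.intersects(inst.bbox) and mask_iou(tip_cell, inst) > 0:
                hits.append(i)
                tip_hits[i].append(j)
        overlaps[j] = hits

    unique: list[tuple[Branch, CellInstance]] = []
    orphans: list[CellInstance] = []
    contested_nodes: set[tuple[str, int]] = set()

    for j, hits in overlaps.items():
        if not hits:
            orphans.append(cur.instances[j])
        elif len(hits) == 1 and len(tip_hits[hits[0]]) == 1:
            unique.append((prev_tips[hits[0]], cur.instances[j]))
        else:
            contested_nodes.add(("inst", j))
            for i in hits:
                contested_nodes.add(("tip", i))

    # connected components of the contested bipartite subgraph
    groups: list[tuple[list[Branch], list[CellInstance]]] = []
    seen: set[tuple[str, int]] = set()
    for start in sorted(contested_nodes, key=lambda n: (n[0], n[1])):
        if start in seen:
            continue
        stack = [start]
        comp_tips: set[int] = set()
        comp_insts: set[int] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            kind, idx = node
            if kind == "inst":
                comp_insts.add(idx)
                stack.extend(("tip", i) for i in overlaps[idx])
            else:
                comp_tips.add(idx)
                stack.extend(
                    ("inst", j) for j in tip_hits[idx] if ("inst", j) in contested_nodes
                )
        if comp_insts:
            groups.append(
                (
                    [prev_tips[i] for i in sorted(comp_tips)],
                    [cur.instances[j] for j in sorted(comp_insts)],
                )
            )
    return unique, groups, orphans


def resolve_contested(
    tips: Sequence[Branch],
    instances: Sequence[CellInstance],
    weights: Sequence[float],
) -> tuple[list[tuple[Branch, CellInstance, float]], list[Branch], list[CellInstance]]:
    """Greedy one-to-one assignment by descending similarity total.

    Exact ties are broken by smallest instance id, then smallest branch id.
    Returns ``(links, unmatched_tips, unmatched_instances)``.
    """
    pairs = []
    for ti, branch in enumerate(tips):
        for inst in instances:
            sim = similarity_index(branch.tip.cell, inst, weights)
            pairs.append((sim.total, inst.instance_id, branch.branch_id, ti, inst))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_tips: set[int] = set()
    used_insts: set[int] = set()
    links = []
    for total, iid, _bid, ti, inst in pairs:
        if ti in used_tips or iid in used_insts:
            continue
        used_tips.add(ti)
        used_insts.add(iid)
        links.append((tips[ti], inst, total))
    unmatched_tips = [b for ti, b in enumerate(tips) if ti not in used_tips]
    unmatched = [c for c in instances if c.instance_id not in used_insts]
    return links, unmatched_tips, unmatched


def expanded_search_candidates(
    orphan: CellInstance,
    tips: Sequence[Branch],
    alpha: float,
    image_shape: Optional[tuple[int, int]] = None,
    weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0),
) -> list[tuple[Branch, float]]:
    """Tips whose centroid falls inside the orphan's expanded box, best first."""
    box = expand_bbox(orphan.bbox, alpha, image_shape)
    out = []
    for branch in tips:
        cx, cy = branch.tip.cell.centroid
        if box.contains(cx, cy):
            sim = similarity_index(branch.tip.cell, orphan, weights)
            out.append((branch, sim.total))
    out.sort(key=lambda t: (-t[1], t[0].branch_id))
    return out


def detect_division(
    orphan: CellInstance,
    tips: Sequence[Branch],
    config: TrackerConfig,
    frame: int,
    image_shape: Optional[tuple[int, int]] = None,
    use_class: bool = False,
) -> Optional[Branch]:
    """Find a compatible mother branch for an unlinked instance, or None.

    A tip qualifies as mother iff its cell in the previous frame is at least
    ``division_size_ratio`` times the orphan's area, its lineage has not
    divided within ``division_cooldown`` frames, and its centroid lies inside
    the orphan's expanded bounding box.  In class-aware mode the mother's raw
    class must additionally be the mitotic label.  Among several qualifying
    mothers the highest similarity wins.
    """
    box = expand_bbox(orphan.bbox, config.alpha, image_shape)
    candidates = []
    for branch in tips:
        # the mother's node in the previous frame (the branch may already
        # carry a provisionally linked continuation at the current frame)
        mother_node = next(
            (n for n in reversed(branch.nodes) if n.frame == frame - 1), None
        )
        if mother_node is None:
            continue
        mother = mother_node.cell
        if mother.area < config.division_size_ratio * orphan.area:
            continue
        last_div = branch.last_division_frame
        if last_div is not None and frame - last_div <= config.division_cooldown:
            continue
        if not box.contains(*mother.centroid):
            continue
        if use_class and mother_node.raw_class != M_PHASE_LABEL:
            continue
        sim = similarity_index(mother, orphan, config.weights)
        candidates.append((sim.total, branch.branch_id, branch))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return candidates[0][2]


def cache_match(
    orphan: CellInstance,
    branches: Sequence[Branch],
    frame: int,
    config: TrackerConfig,
    image_shape: Optional[tuple[int, int]] = None,
) -> Optional[Branch]:
    """Relink an orphan to a branch that ended within ``cache_depth`` frames."""
    box = expand_bbox(orphan.bbox, config.alpha, image_shape)
    candidates = []
    for branch in branches:
        age = frame - branch.end_frame
        if not (1 <= age <= config.cache_depth):
            continue
        if not box.contains(*branch.tip.cell.centroid):
            continue
        sim = similarity_index(branch.tip.cell, orphan, config.weights)
        candidates.append((sim.total, branch.branch_id, branch))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return candidates[0][2]


def _frames_have_class(frames: Sequence[FrameSegmentation]) -> bool:
    return any(inst.class_label is not None for fs in frames for inst in fs.instances)


def track(
    frames: Sequence[FrameSegmentation], config: Optional[TrackerConfig] = None
) -> TrackForest:
    """Run the full cascade over a frame sequence and return the raw forest.

    The forest carries the per-instance :class:`LinkDecision` audit trail in
    ``forest.decisions``.  Refinement (pruning, fragment linking, gap filling)
    is a separate step.
    """
    config = config or TrackerConfig()
    forest = TrackForest()
    if not frames:
        return forest

    if config.use_class_for_division == "on":
        use_class = True
    elif config.use_class_for_division == "off":
        use_class = False
    else:
        use_class = _frames_have_class(frames)

    decisions: list[LinkDecision] = []
    # branch -> node added this frame, for division daughter re-labelling
    first = frames[0]
    for inst in sorted(first.instances, key=lambda c: c.instance_id):
        tree = forest.new_tree(inst)
        decisions.append(
            LinkDecision(first.frame, inst.instance_id, "new_tree",
                         branch_id=tree.root_branch_id)
        )

    for fs in frames[1:]:
        f = fs.frame
        shape = fs.image_shape
        open_branches = [
            b for b in forest.iter_branches() if not b.closed and b.nodes
        ]
        prev_tips = [b for b in open_branches if b.end_frame == f - 1]
        decided: dict[int, LinkDecision] = {}
        linked_this_frame: dict[int, CellInstance] = {}  # branch_id -> instance

        def commit_link(branch: Branch, inst: CellInstance, outcome: str,
                        sim: Optional[float] = None) -> None:
            tree = forest.trees[branch.tree_id]
            tree.add_node(branch.branch_id, inst)
            linked_this_frame[branch.branch_id] = inst
            decided[inst.instance_id] = LinkDecision(
                f, inst.instance_id, outcome, branch_id=branch.branch_id, similarity=sim
            )

        unique, groups, orphans = link_by_overlap(prev_tips, fs)
        for branch, inst in unique:
            commit_link(branch, inst, "linked_unique")
        for tips, insts in groups:
            links, _, leftover = resolve_contested(tips, insts, config.weights)
            for branch, inst, total in links:
                commit_link(branch, inst, "linked_by_similarity", total)
                logger.info(
                    "frame %d: instance %d linked to branch %d by similarity %.4g",
                    f, inst.instance_id, branch.branch_id, total,
                )
            orphans.extend(leftover)
        orphans.sort(key=lambda c: c.instance_id)

        # tier 3: expanded-box search against still-unmatched previous tips
        unmatched_tips = [
            b for b in prev_tips if b.branch_id not in linked_this_frame
        ]
        pairs = []
        for orphan in orphans:
            for branch, total in expanded_search_candidates(
                orphan, unmatched_tips, config.alpha, shape, config.weights
            ):
                pairs.append((total, orphan.instance_id, branch.branch_id, branch, orphan))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        expanded_linked: set[int] = set()
        for total, iid, bid, branch, orphan in pairs:
            if iid in expanded_linked or bid in linked_this_frame:
                continue
            commit_link(branch, orphan, "linked_expanded", total)
            expanded_linked.add(iid)
            logger.info(
                "frame %d: orphan %d linked to branch %d via expanded search",
                f, iid, bid,
            )
        orphans = [c for c in orphans if c.instance_id not in expanded_linked]

        # tier 4: division detection; daughters are the orphan plus the
        # instance linked to the mother this frame (no continuation -> reject)
        remaining = []
        for orphan in orphans:
            mother_candidates = [
                b for b in prev_tips
                if b.branch_id in linked_this_frame and not b.closed
            ]
            mother = detect_division(orphan, mother_candidates, config, f, shape, use_class)
            if mother is None:
                remaining.append(orphan)
                continue
            sibling = linked_this_frame.pop(mother.branch_id)
            mother.nodes.pop()  # undo the provisional same-frame link
            tree = forest.trees[mother.tree_id]
            bid_a, bid_b = tree.open_division(
                mother.branch_id, sibling, orphan, f,
                (forest.new_branch_id(), forest.new_branch_id()),
            )
            linked_this_frame[bid_a] = sibling
            linked_this_frame[bid_b] = orphan
            decided[sibling.instance_id] = LinkDecision(
                f, sibling.instance_id, "division_daughter", branch_id=bid_a
            )
            decided[orphan.instance_id] = LinkDecision(
                f, orphan.instance_id, "division_daughter", branch_id=bid_b
            )
            logger.info(
                "frame %d: division of branch %d into %d/%d (daughters %d, %d)",
                f, mother.branch_id, bid_a, bid_b,
                sibling.instance_id, orphan.instance_id,
            )
        orphans = remaining

        # tier 5: cache matching against branches that ended a few frames ago
        remaining = []
        for orphan in orphans:
            cache_pool = [
                b for b in open_branches
                if b.branch_id not in linked_this_frame and not b.closed
            ]
            branch = cache_match(orphan, cache_pool, f, config, shape)
            if branch is None:
                remaining.append(orphan)
                continue
            commit_link(branch, orphan, "cache_relinked")
            logger.info(
                "frame %d: orphan %d relinked to cached branch %d (gap %d)",
                f, orphan.instance_id, branch.branch_id, f - branch.nodes[-2].frame,
            )
        orphans = remaining

        # tier 6: new trees
        for orphan in orphans:
            tree = forest.new_tree(orphan)
            decided[orphan.instance_id] = LinkDecision(
                f, orphan.instance_id, "new_tree", branch_id=tree.root_branch_id
            )
            logger.info("frame %d: instance %d starts tree %d",
                        f, orphan.instance_id, tree.tree_id)

        decisions.extend(decided[iid] for iid in sorted(decided))

    forest.decisions = decisions
    return forest
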