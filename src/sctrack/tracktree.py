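"""Lineage-tree data structures.

A :class:`TrackTree` is a binary lineage tree: each branch is the per-frame
node sequence of one tracked cell, and a branching is a division event that
closes the mother branch and opens exactly two daughter branches.  A
:class:`TrackForest` holds all trees of a movie with globally unique tree and
branch ids assigned by deterministic incrementing counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import OrderingError, StateError
from .features import CellInstance

__all__ = [
    "TrackNode",
    "Branch",
    "TrackTree",
    "TrackForest",
    "LineageRecord",
    "export_lineage",
]


@dataclass
class TrackNode:
    """One node: a cell instance observed (or gap-filled) at one frame."""

    cell: CellInstance
    branch_id: int
    is_gap_fill: bool = False
    raw_class: Optional[str] = None
    smoothed_class: Optional[str] = None

    @property
    def frame(self) -> int:
        return self.cell.frame


@dataclass
class Branch:
    """A maximal division-free node sequence within a tree."""

    branch_id: int
    tree_id: int
    parent_branch_id: Optional[int] = None
    nodes: list[TrackNode] = field(default_factory=list)
    child_branch_ids: list[int] = field(default_factory=list)
    #: frame of the division that created this branch (None for roots); also
    #: the cooldown reference inherited by the lineage
    last_division_frame: Optional[int] = None
    closed: bool = False  # True once the branch ended in a division

    @property
    def tip(self) -> TrackNode:
        return self.nodes[-1]

    @property
    def start_frame(self) -> int:
        return self.nodes[0].frame

    @property
    def end_frame(self) -> int:
        return self.nodes[-1].frame


class TrackTree:
    """One lineage tree; branches are stored in a dict keyed by branch id."""

    def __init__(self, tree_id: int):
        self.tree_id = tree_id
        self.branches: dict[int, Branch] = {}
        self.root_branch_id: Optional[int] = None

    # -- construction ------------------------------------------------------

    def add_branch(self, branch: Branch) -> None:
        branch.tree_id = self.tree_id
        self.branches[branch.branch_id] = branch
        if branch.parent_branch_id is None and self.root_branch_id is None:
            self.root_branch_id = branch.branch_id

    def add_node(self, branch_id: int, cell: CellInstance, is_gap_fill: bool = False) -> TrackNode:
        """Append a cell to a branch; frames must strictly increase."""
        branch = self.branches[branch_id]
        if branch.closed:
            raise StateError(f"branch {branch_id} is closed by a division")
        if branch.nodes and cell.frame <= branch.end_frame:
            raise OrderingError(
                f"cell frame {cell.frame} not after branch tip frame {branch.end_frame}"
            )
        node = TrackNode(
            cell=cell,
            branch_id=branch_id,
            is_gap_fill=is_gap_fill,
            raw_class=cell.class_label,
        )
        branch.nodes.append(node)
        return node

    def open_division(
        self,
        mother_branch_id: int,
        daughter_a: CellInstance,
        daughter_b: CellInstance,
        frame: int,
        new_branch_ids: tuple[int, int],
    ) -> tuple[int, int]:
        """Close the mother branch at ``frame - 1`` and open two daughters at ``frame``."""
        mother = self.branches[mother_branch_id]
        if mother.closed:
            raise StateError(f"branch {mother_branch_id} already closed by a division")
        if not mother.nodes or mother.end_frame != frame - 1:
            raise StateError(
                f"mother branch tip at frame {mother.end_frame if mother.nodes else None}, "
                f"expected {frame - 1} for a division at frame {frame}"
            )
        mother.closed = True
        ids = []
        for bid, cell in zip(new_branch_ids, (daughter_a, daughter_b)):
            child = Branch(
                branch_id=bid,
                tree_id=self.tree_id,
                parent_branch_id=mother_branch_id,
                last_division_frame=frame,
            )
            self.add_branch(child)
            self.add_node(bid, cell)
            mother.child_branch_ids.append(bid)
            ids.append(bid)
        return (ids[0], ids[1])

    # -- queries -----------------------------------------------------------

    def iter_nodes(self) -> Iterator[TrackNode]:
        for bid in sorted(self.branches):
            yield from self.branches[bid].nodes

    def n_nodes(self, real_only: bool = False) -> int:
        return sum(
            1 for n in self.iter_nodes() if not (real_only and n.is_gap_fill)
        )

    def leaves(self) -> list[Branch]:
        return [b for b in self.branches.values() if not b.child_branch_ids]

    def start_frame(self) -> int:
        return min(b.start_frame for b in self.branches.values() if b.nodes)

    def end_frame(self) -> int:
        return max(b.end_frame for b in self.branches.values() if b.nodes)

    def span(self) -> int:
        """Last frame - first frame + 1 over all nodes."""
        if not self.branches:
            raise StateError("span of an empty tree")
        return self.end_frame() - self.start_frame() + 1


def tree_span(tree: TrackTree) -> int:
    return tree.span()


class TrackForest:
    """All lineage trees of one movie."""

    def __init__(self) -> None:
        self.trees: dict[int, TrackTree] = {}
        self._next_tree_id = 1
        self._next_branch_id = 1
        self.decisions: list = []  # LinkDecision audit trail, filled by the tracker

    def new_branch_id(self) -> int:
        bid = self._next_branch_id
        self._next_branch_id += 1
        return bid

    def new_tree(self, cell: CellInstance) -> TrackTree:
        tree = TrackTree(self._next_tree_id)
        self._next_tree_id += 1
        branch = Branch(branch_id=self.new_branch_id(), tree_id=tree.tree_id)
        tree.add_branch(branch)
        tree.add_node(branch.branch_id, cell)
        self.trees[tree.tree_id] = tree
        return tree

    def remove_tree(self, tree_id: int) -> TrackTree:
        return self.trees.pop(tree_id)

    def iter_branches(self) -> Iterator[Branch]:
        for tid in sorted(self.trees):
            for bid in sorted(self.trees[tid].branches):
                yield self.trees[tid].branches[bid]

    def iter_nodes(self) -> Iterator[TrackNode]:
        for branch in self.iter_branches():
            yield from branch.nodes

    def n_nodes(self, real_only: bool = False) -> int:
        return sum(1 for n in self.iter_nodes() if not (real_only and n.is_gap_fill))

    def branch(self, branch_id: int) -> Branch:
        for tree in self.trees.values():
            if branch_id in tree.branches:
                return tree.branches[branch_id]
        raise KeyError(branch_id)

    def has_class_labels(self) -> bool:
        return any(n.raw_class is not None for n in self.iter_nodes())


@dataclass(frozen=True)
class LineageRecord:
    """One flat output row per node."""

    frame: int
    tree_id: int
    branch_id: int
    parent_branch_id: Optional[int]
    instance_id: int
    centroid_x: float
    centroid_y: float
    area: float
    raw_class: Optional[str]
    smoothed_class: Optional[str]
    is_gap_fill: bool


def export_lineage(forest: TrackForest) -> list[LineageRecord]:
    """Flatten a forest to records sorted by (frame, tree_id, branch_id)."""
    records = []
    for tid in sorted(forest.trees):
        tree = forest.trees[tid]
        for bid in sorted(tree.branches):
            branch = tree.branches[bid]
            for node in branch.nodes:
                records.append(
                    LineageRecord(
                        frame=node.frame,
                        tree_id=tid,
                        branch_id=bid,
                        parent_branch_id=branch.parent_branch_id,
                        instance_id=node.cell.instance_id,
                        centroid_x=node.cell.centroid[0],
                        centroid_y=node.cell.centroid[1],
                        area=node.cell.area,
                        raw_class=node.raw_class,
                        smoothed_class=node.smoothed_class,
                        is_gap_fill=node.is_gap_fill,
                    )
                )
    records.sort(key=lambda r: (r.frame, r.tree_id, r.branch_id))
    return records
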