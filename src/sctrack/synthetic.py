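"""Ground-truthed synthetic time-lapse generator.

Cells are rasterized ellipses performing a Gaussian random walk small enough
that consecutive masks overlap.  Scheduled mothers swell and carry the
mitotic label for the frames preceding division, then split into two adjacent
daughters of ~55% the mother's area (so the 1.3x mother/daughter size rule
holds with margin).  Corruption (detection dropout, single-frame false
positives, label noise) is applied separately so the ground-truth forest
stays exact.  All randomness flows through one seeded generator; runs are
bit-identical per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from skimage import draw as _draw

from .errors import ConfigurationError
from .features import CellInstance, FrameSegmentation, _instance_from_pixels
from .metrics import DivisionEvent
from .tracktree import TrackForest

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_timelapse",
    "corrupt_dropout_fp",
    "corrupt_classes",
    "division_protection_keys",
]

#: Default cell-cycle schedule: (label, run length), cycled.  The mitotic
#: label is forced onto the frames just before a division.
DEFAULT_CYCLE = (("G1/G2", 20), ("S", 15), ("G1/G2", 40))

M_LABEL = "M"
M_DURATION = 8  # frames of mitotic label before the division frame


@dataclass
class SimulationConfig:
    n_cells: int = 20
    n_frames: int = 100
    image_shape: tuple[int, int] = (640, 640)
    motion_sigma: float = 2.0
    radius_mean: float = 12.0
    radius_sd: float = 1.5
    n_divisions: int = 0
    #: explicit {cell_index: frame}; overrides n_divisions when given
    division_schedule: Optional[dict[int, int]] = None
    daughter_area_fraction: float = 0.55
    with_classes: bool = False
    cycle: tuple = DEFAULT_CYCLE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 1:
            raise ConfigurationError("need at least one cell and one frame")
        if not (0.0 < self.daughter_area_fraction < 1.0 / 1.3):
            raise ConfigurationError(
                "daughter_area_fraction must be in (0, 1/1.3) to satisfy the size rule"
            )

    @property
    def cycle_length(self) -> int:
        return sum(d for _, d in self.cycle)


class _SimCell:
    """Mutable simulation state of one cell."""

    def __init__(self, cid, center, radii, angle, phase_offset, born_at=0,
                 sibling_cid=None):
        self.cid = cid
        self.center = np.asarray(center, dtype=float)  # (row, col)
        self.radii = np.asarray(radii, dtype=float)  # (r_radius, c_radius)
        self.angle = float(angle)
        self.phase_offset = int(phase_offset)
        self.born_at = born_at
        self.sibling_cid = sibling_cid
        self.alive = True
        self.division_frame: Optional[int] = None
        self.branch_id: Optional[int] = None

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())


def _cycle_label(cycle, t: int) -> str:
    total = sum(d for _, d in cycle)
    t = t % total
    for label, dur in cycle:
        if t < dur:
            return label
        t -= dur
    return cycle[-1][0]  # pragma: no cover


def _true_label(cell: _SimCell, frame: int, cfg: SimulationConfig) -> Optional[str]:
    if not cfg.with_classes:
        return None
    if cell.division_frame is not None:
        if cell.division_frame - M_DURATION <= frame < cell.division_frame:
            return M_LABEL
    return _cycle_label(cfg.cycle, frame + cell.phase_offset)


def _place_initial(rng, cfg) -> list[_SimCell]:
    h, w = cfg.image_shape
    margin = 3.0 * cfg.radius_mean
    # keep unrelated cells out of each other's expanded-search reach
    min_sep = 8.0 * cfg.radius_mean
    centers: list[np.ndarray] = []
    cells = []
    for cid in range(cfg.n_cells):
        for _ in range(5000):
            c = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(np.linalg.norm(c - other) >= min_sep for other in centers):
                centers.append(c)
                break
        else:
            raise ConfigurationError(
                f"cannot pack {cfg.n_cells} cells into image {cfg.image_shape}"
            )
        radii = np.clip(
            rng.normal(cfg.radius_mean, cfg.radius_sd, size=2),
            0.75 * cfg.radius_mean,
            1.25 * cfg.radius_mean,
        )
        cells.append(
            _SimCell(cid, centers[-1], radii, rng.uniform(0, np.pi),
                     phase_offset=int(rng.integers(0, cfg.cycle_length)))
        )
    return cells


#: frames after birth during which daughters actively migrate apart
_REPEL_FRAMES = 12
_REPEL_STEP = 2.5


def _step(cell: _SimCell, frame: int, all_cells: Sequence[_SimCell], rng, cfg) -> None:
    h, w = cfg.image_shape
    margin = 2.0 * cell.max_radius + 2.0
    drift = np.zeros(2)
    if cell.sibling_cid is not None and frame - cell.born_at <= _REPEL_FRAMES:
        sibling = next((o for o in all_cells if o.cid == cell.sibling_cid), None)
        if sibling is not None:
            away = cell.center - sibling.center
            norm = np.linalg.norm(away)
            if norm > 1e-6:
                drift = _REPEL_STEP * away / norm
    for _ in range(10):
        proposal = cell.center + drift + rng.normal(0.0, cfg.motion_sigma, size=2)
        if not (margin <= proposal[0] <= h - margin and margin <= proposal[1] <= w - margin):
            continue
        # generous clearance keeps every non-sibling neighbour outside the
        # tracker's expanded search box, as in sparsely plated cultures
        clear = all(
            np.linalg.norm(proposal - o.center)
            > 2.0 * (cell.max_radius + o.max_radius) + 2.0
            for o in all_cells
            if o.alive and o.cid != cell.cid and o.cid != cell.sibling_cid
        ) and all(
            np.linalg.norm(proposal - o.center)
            > 1.1 * (cell.max_radius + o.max_radius) + 2.0
            for o in all_cells
            if o.alive and o.cid == cell.sibling_cid
        )
        if clear:
            cell.center = proposal
            return
    # stay put rather than collide


def _raster_cell(cell: _SimCell, frame: int, cfg: SimulationConfig):
    radii = cell.radii
    if (
        cell.division_frame is not None
        and cell.division_frame - M_DURATION <= frame < cell.division_frame
    ):
        radii = cell.radii * 1.15  # mitotic swelling
    return _draw.ellipse(
        cell.center[0], cell.center[1], radii[0], radii[1],
        shape=cfg.image_shape, rotation=cell.angle,
    )


def simulate_timelapse(
    config: Optional[SimulationConfig] = None,
) -> tuple[list[FrameSegmentation], TrackForest, list[DivisionEvent]]:
    """Generate frames plus the exact ground-truth forest and division list."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    cells = _place_initial(rng, cfg)

    schedule = dict(cfg.division_schedule or {})
    if not schedule and cfg.n_divisions:
        if cfg.n_divisions > cfg.n_cells:
            raise ConfigurationError("more divisions than cells")
        lo = min(M_DURATION + 12, max(1, cfg.n_frames // 3))
        hi = max(lo + 1, cfg.n_frames - 10)
        dividers = rng.choice(cfg.n_cells, size=cfg.n_divisions, replace=False)
        frames_chosen = rng.choice(np.arange(lo, hi), size=cfg.n_divisions, replace=False)
        schedule = {int(c): int(f) for c, f in zip(dividers, frames_chosen)}
    for cid, f in schedule.items():
        if not (1 <= f < cfg.n_frames):
            raise ConfigurationError(f"division frame {f} outside movie")
        cells[cid].division_frame = f
        # align the cycle so the mitotic label begins at a schedule boundary
        cells[cid].phase_offset = (M_DURATION - f) % cfg.cycle_length

    forest = TrackForest()
    truth_divisions: list[DivisionEvent] = []
    frames: list[FrameSegmentation] = []
    next_cid = cfg.n_cells
    #: long steady block of the default cycle; daughters restart there
    daughter_anchor = cfg.cycle[0][1] + cfg.cycle[1][1] if len(cfg.cycle) > 2 else 0

    for f in range(cfg.n_frames):
        # 1. divisions scheduled for this frame
        divisions_now: list[tuple[int, _SimCell, _SimCell]] = []
        for cell in list(cells):
            if not (cell.alive and cell.division_frame == f):
                continue
            d_radii = np.sqrt(cfg.daughter_area_fraction) * cell.radii
            axis = rng.uniform(0, np.pi)
            offset = (float(d_radii.max()) + 1.5) * np.array([np.sin(axis), np.cos(axis)])
            h, w = cfg.image_shape
            daughters = []
            for sign in (+1, -1):
                d = _SimCell(
                    next_cid,
                    np.clip(
                        cell.center + sign * offset,
                        [2 * d_radii.max() + 2] * 2,
                        [h - 2 * d_radii.max() - 2, w - 2 * d_radii.max() - 2],
                    ),
                    d_radii,
                    rng.uniform(0, np.pi),
                    phase_offset=(daughter_anchor - f) % cfg.cycle_length,
                    born_at=f,
                )
                next_cid += 1
                daughters.append(d)
            daughters[0].sibling_cid = daughters[1].cid
            daughters[1].sibling_cid = daughters[0].cid
            cell.alive = False
            cells.extend(daughters)
            divisions_now.append((cell.branch_id, daughters[0], daughters[1]))

        live = [c for c in cells if c.alive]

        # 2. move everything alive before this frame
        if f > 0:
            for cell in live:
                if cell.born_at < f:
                    _step(cell, f, live, rng, cfg)

        # 3. rasterize
        inst_by_cid: dict[int, CellInstance] = {}
        instances = []
        for cell in sorted(live, key=lambda c: c.cid):
            rr, cc = _raster_cell(cell, f, cfg)
            if rr.size == 0:  # pragma: no cover - cells are kept in bounds
                continue
            inst = _instance_from_pixels(
                rr, cc, frame=f, instance_id=cell.cid + 1,
                class_label=_true_label(cell, f, cfg),
            )
            inst_by_cid[cell.cid] = inst
            instances.append(inst)

        # 4. grow the truth forest
        for mother_bid, d0, d1 in divisions_now:
            mother_branch = forest.branch(mother_bid)
            tree = forest.trees[mother_branch.tree_id]
            bid_a, bid_b = forest.new_branch_id(), forest.new_branch_id()
            tree.open_division(
                mother_bid, inst_by_cid[d0.cid], inst_by_cid[d1.cid], f, (bid_a, bid_b)
            )
            d0.branch_id, d1.branch_id = bid_a, bid_b
            truth_divisions.append(
                DivisionEvent(frame=f, mother=mother_bid,
                              daughter_a=min(bid_a, bid_b), daughter_b=max(bid_a, bid_b))
            )
        for cell in sorted(live, key=lambda c: c.cid):
            if cell.cid not in inst_by_cid:
                continue  # pragma: no cover
            if cell.branch_id is None:
                tree = forest.new_tree(inst_by_cid[cell.cid])
                cell.branch_id = tree.root_branch_id
            elif cell.born_at < f:
                branch = forest.branch(cell.branch_id)
                forest.trees[branch.tree_id].add_node(
                    cell.branch_id, inst_by_cid[cell.cid]
                )
            # daughters born this frame were added by open_division above

        frames.append(
            FrameSegmentation(frame=f, instances=instances, image_shape=cfg.image_shape)
        )

    return frames, forest, truth_divisions


def corrupt_dropout_fp(
    frames: Sequence[FrameSegmentation],
    p: float = 0.0,
    q: float = 0.0,
    seed: int = 0,
    protect: Optional[set] = None,
    fp_frames: Optional[Sequence[int]] = None,
) -> list[FrameSegmentation]:
    """Delete each instance with probability ``p`` and add Poisson(``q``)
    single-frame false-positive blobs per frame.

    ``protect`` is an optional set of ``(frame, instance_id)`` keys exempt
    from dropout (used to keep fixtures repairable, e.g. around divisions).
    ``fp_frames`` lists frames that each receive exactly one additional blob
    (for fixtures needing a deterministic false-positive count).  The input
    frames are not mutated; the ground truth is untouched.
    """
    if not (0.0 <= p <= 1.0) or q < 0:
        raise ConfigurationError("dropout probability must be in [0, 1], fp rate >= 0")
    rng = np.random.default_rng(seed)
    protect = protect or set()
    fp_frames = list(fp_frames or [])
    out = []
    fp_id = 100000
    for fs in frames:
        kept = []
        for inst in fs.instances:
            if inst.key not in protect and rng.random() < p:
                continue
            kept.append(inst)
        n_fp = int(rng.poisson(q)) + fp_frames.count(fs.frame)
        shape = fs.image_shape or (512, 512)
        for _ in range(n_fp):
            for _attempt in range(50):
                center = rng.uniform([10, 10], [shape[0] - 10, shape[1] - 10])
                radius = rng.uniform(3.0, 5.0)
                clear = all(
                    np.hypot(center[1] - k.centroid[0], center[0] - k.centroid[1])
                    > radius + 70.0
                    for k in kept
                )
                if clear:
                    rr, cc = _draw.ellipse(center[0], center[1], radius, radius, shape=shape)
                    if rr.size:
                        kept.append(
                            _instance_from_pixels(rr, cc, frame=fs.frame, instance_id=fp_id)
                        )
                        fp_id += 1
                    break
        kept.sort(key=lambda c: c.instance_id)
        out.append(FrameSegmentation(frame=fs.frame, instances=kept, image_shape=fs.image_shape))
    return out


def corrupt_classes(
    frames: Sequence[FrameSegmentation],
    r: float,
    seed: int = 0,
    confusion: Optional[dict[str, dict[str, float]]] = None,
) -> list[FrameSegmentation]:
    """Replace each class label with probability ``r`` by a different class.

    The replacement is drawn uniformly from the other observed classes, or
    per-class ``confusion`` weights when given.  Frames are not mutated.
    """
    if not (0.0 <= r <= 1.0):
        raise ConfigurationError("class noise rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vocab = sorted(
        {i.class_label for fs in frames for i in fs.instances if i.class_label}
    )
    out = []
    for fs in frames:
        instances = []
        for inst in fs.instances:
            label = inst.class_label
            if label is not None and len(vocab) > 1 and rng.random() < r:
                if confusion and label in confusion:
                    options = sorted(confusion[label])
                    weights = np.array([confusion[label][o] for o in options], float)
                    label = str(rng.choice(options, p=weights / weights.sum()))
                else:
                    others = [c for c in vocab if c != label]
                    label = others[int(rng.integers(len(others)))]
                inst = replace(inst, class_label=label)
            instances.append(inst)
        out.append(FrameSegmentation(frame=fs.frame, instances=instances,
                                     image_shape=fs.image_shape))
    return out


def division_protection_keys(
    truth: TrackForest,
    truth_divisions: Sequence[DivisionEvent],
    pad: int = 2,
) -> set[tuple[int, int]]:
    """Detection keys near divisions (mother's last ``pad`` frames, daughters'
    first ``pad``) whose dropout would make a division unrecoverable."""
    keys: set[tuple[int, int]] = set()
    for event in truth_divisions:
        mother = truth.branch(event.mother)
        for node in mother.nodes[-pad:]:
            keys.add(node.cell.key)
        for bid in (event.daughter_a, event.daughter_b):
            for node in truth.branch(bid).nodes[:pad]:
                keys.add(node.cell.key)
    return keys
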