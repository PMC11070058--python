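"""Readers and writers: label-mask TIFF stacks, VIA2 polygon JSON, lineage
CSV tables, and tracked-mask TIFF output.

Frame ordering is deterministic everywhere: multi-page TIFFs keep page
order, directories and VIA image entries are natural-sorted on filename
(numeric runs compared as numbers).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile

from .errors import FormatError
from .features import (
    CellInstance,
    FrameSegmentation,
    extract_instances,
    instance_from_polygon,
)
from .tracktree import LineageRecord, TrackForest

logger = logging.getLogger(__name__)

__all__ = [
    "read_label_stack",
    "read_via_json",
    "write_via_json",
    "write_lineage_csv",
    "read_lineage_csv",
    "write_tracked_masks",
]

PathLike = Union[str, Path]

LINEAGE_HEADER = [
    "frame", "tree_id", "branch_id", "parent_branch_id", "instance_id",
    "centroid_x", "centroid_y", "area", "raw_class", "smoothed_class",
    "is_gap_fill",
]


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", name)]


def _load_pages(path: PathLike) -> list[np.ndarray]:
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        logger.info("reading %d frames from %s (natural filename sort)", len(files), path)
        pages = [tifffile.imread(f) for f in files]
    else:
        data = tifffile.imread(path)
        pages = [data] if data.ndim == 2 else list(data)
    shapes = {p.shape for p in pages}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent frame shapes: {sorted(shapes)}")
    return pages


def read_label_stack(
    path: PathLike,
    intensity_path: Optional[PathLike] = None,
    hu_transform: str = "log",
) -> list[FrameSegmentation]:
    """Read a multi-page TIFF (or directory of TIFFs) of integer label masks."""
    pages = _load_pages(path)
    intensity_pages = None
    if intensity_path is not None:
        intensity_pages = _load_pages(intensity_path)
        if len(intensity_pages) != len(pages):
            raise FormatError("intensity stack has a different frame count")
    frames = []
    for f, page in enumerate(pages):
        if not np.issubdtype(page.dtype, np.integer):
            raise FormatError(
                f"label mask page {f} has non-integer dtype {page.dtype}"
            )
        frames.append(
            extract_instances(
                page, frame=f,
                intensity_image=None if intensity_pages is None else intensity_pages[f],
                hu_transform=hu_transform,
            )
        )
    return frames


def _via_metadata(doc: dict) -> dict:
    if "_via_img_metadata" in doc:
        return doc["_via_img_metadata"]
    return doc


def read_via_json(
    path: PathLike,
    class_key: str = "phase",
    hu_transform: str = "log",
) -> list[FrameSegmentation]:
    """Read a VIA2-compatible annotation JSON; one image entry per frame."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    meta = _via_metadata(doc)
    entries = sorted(
        meta.values(), key=lambda e: _natural_key(str(e.get("filename", "")))
    )
    frames = []
    for f, entry in enumerate(entries):
        instances = []
        regions = entry.get("regions", [])
        if isinstance(regions, dict):  # older VIA dialect: dict keyed by index
            regions = [regions[k] for k in sorted(regions, key=_natural_key)]
        for i, region in enumerate(regions, start=1):
            shape = region.get("shape_attributes", {})
            xs = shape.get("all_points_x")
            ys = shape.get("all_points_y")
            if xs is None or ys is None:
                raise FormatError(
                    f"{path.name}: frame {f} region {i} lacks polygon coordinates"
                )
            if len(xs) != len(ys):
                raise FormatError(
                    f"{path.name}: frame {f} region {i}: "
                    f"all_points_x ({len(xs)}) != all_points_y ({len(ys)})"
                )
            cls = region.get("region_attributes", {}).get(class_key)
            instances.append(
                instance_from_polygon(
                    xs, ys, frame=f, instance_id=i,
                    class_label=cls, hu_transform=hu_transform,
                )
            )
        frames.append(FrameSegmentation(frame=f, instances=instances))
    return frames


def write_via_json(
    source: Union[Sequence[FrameSegmentation], TrackForest],
    path: PathLike,
    class_key: str = "phase",
) -> None:
    """Write frames (or a tracked forest) as VIA2-compatible JSON.

    Forest input additionally records tree/branch ids as region attributes.
    ``read_via_json(write_via_json(frames))`` reproduces contours and classes
    exactly.
    """
    if isinstance(source, TrackForest):
        by_frame: dict[int, list] = {}
        for branch in source.iter_branches():
            for node in branch.nodes:
                by_frame.setdefault(node.frame, []).append(
                    (node.cell, {"tree_id": str(branch.tree_id),
                                 "branch_id": str(branch.branch_id),
                                 "is_gap_fill": str(int(node.is_gap_fill))})
                )
        items = [(f, by_frame[f]) for f in sorted(by_frame)]
    else:
        items = [
            (fs.frame, [(inst, {}) for inst in fs.instances]) for fs in source
        ]

    metadata = {}
    for f, cells in items:
        filename = f"frame_{f:05d}.png"
        regions = []
        for cell, extra in sorted(cells, key=lambda t: t[0].instance_id):
            attrs = dict(extra)
            if cell.class_label is not None:
                attrs[class_key] = cell.class_label
            regions.append(
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(x) for x in cell.contour[:, 0]],
                        "all_points_y": [float(y) for y in cell.contour[:, 1]],
                    },
                    "region_attributes": attrs,
                }
            )
        metadata[f"{filename}-1"] = {
            "filename": filename,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    with open(path, "w") as fh:
        json.dump({"_via_img_metadata": metadata}, fh)


def write_lineage_csv(records: Sequence[LineageRecord], path: PathLike) -> None:
    """Write lineage records as CSV (header + one row per node)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LINEAGE_HEADER)
        for r in records:
            writer.writerow([
                r.frame, r.tree_id, r.branch_id,
                "" if r.parent_branch_id is None else r.parent_branch_id,
                r.instance_id,
                repr(r.centroid_x), repr(r.centroid_y), repr(r.area),
                "" if r.raw_class is None else r.raw_class,
                "" if r.smoothed_class is None else r.smoothed_class,
                int(r.is_gap_fill),
            ])


def read_lineage_csv(path: PathLike) -> list[LineageRecord]:
    """Read a lineage CSV back into records."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != LINEAGE_HEADER:
            raise FormatError(
                f"unexpected lineage CSV header {reader.fieldnames} in {path}"
            )
        for row in reader:
            records.append(
                LineageRecord(
                    frame=int(row["frame"]),
                    tree_id=int(row["tree_id"]),
                    branch_id=int(row["branch_id"]),
                    parent_branch_id=(
                        int(row["parent_branch_id"]) if row["parent_branch_id"] else None
                    ),
                    instance_id=int(row["instance_id"]),
                    centroid_x=float(row["centroid_x"]),
                    centroid_y=float(row["centroid_y"]),
                    area=float(row["area"]),
                    raw_class=row["raw_class"] or None,
                    smoothed_class=row["smoothed_class"] or None,
                    is_gap_fill=bool(int(row["is_gap_fill"])),
                )
            )
    return records


def write_tracked_masks(
    forest: TrackForest,
    image_shape: tuple[int, int],
    path: PathLike,
    n_frames: Optional[int] = None,
) -> None:
    """Render the forest as a uint16 multi-page TIFF of tree-id label masks."""
    if n_frames is None:
        n_frames = max((b.end_frame for b in forest.iter_branches()), default=-1) + 1
    stack = np.zeros((max(n_frames, 1), *image_shape), dtype=np.uint16)
    for branch in forest.iter_branches():
        for node in branch.nodes:
            page = stack[node.frame]
            for rr, cc in node.cell.pixels:
                r, c = int(rr), int(cc)
                if 0 <= r < image_shape[0] and 0 <= c < image_shape[1]:
                    if page[r, c] and page[r, c] != branch.tree_id:
                        logger.warning(
                            "frame %d: overlapping masks for trees %d and %d",
                            node.frame, page[r, c], branch.tree_id,
                        )
                    page[r, c] = branch.tree_id
    tifffile.imwrite(path, stack, photometric="minisblack")
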