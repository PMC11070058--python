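"""Per-cell geometric and intensity features from label masks or polygons.

Coordinate convention: 0-based pixel indices with ``x`` = column and
``y`` = row.  Areas and IoU for mask-derived instances are computed on the
rasterized pixel sets; shape moments are computed by exact polygon
integration over the outer contour, which makes them invariant to
translation, rotation and uniform scaling up to floating-point error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from skimage import draw as _draw
from skimage import measure as _skmeasure

from .errors import DegenerateContourError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "CellInstance",
    "FrameSegmentation",
    "expand_bbox",
    "shoelace_area",
    "polygon_hu_moments",
    "hu_log_transform",
    "mask_iou",
    "extract_instances",
    "instance_from_polygon",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with ``x1 < x2`` and ``y1 < y2`` (x = column, y = row)."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate bounding box ({self.x1}, {self.x2}, {self.y1}, {self.y2}): "
                "x1 < x2 and y1 < y2 are required"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        """True when the point lies inside or on the boundary."""
        return self.x1 <= x <= self.x2 and self.y1 <= y <= self.y2

    def intersects(self, other: "BoundingBox") -> bool:
        return not (
            self.x2 < other.x1
            or other.x2 < self.x1
            or self.y2 < other.y1
            or other.y2 < self.y1
        )


def expand_bbox(
    bc: BoundingBox, alpha: float, image_shape: Optional[tuple[int, int]] = None
) -> BoundingBox:
    """Expand a box by ``alpha`` times its own width/height on every side.

    The output is centred like the input with each dimension scaled by
    ``1 + 2*alpha``.  When ``image_shape`` (height, width) is given, the box
    is clipped to ``[0, width-1] x [0, height-1]``.

    Parameters
    ----------
    bc:
        The cell bounding box.
    alpha:
        Nonnegative expansion coefficient (default 1.5 elsewhere).
    image_shape:
        Optional (height, width) used for clipping.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    w = bc.x2 - bc.x1
    h = bc.y2 - bc.y1
    x1 = bc.x1 - alpha * w
    x2 = bc.x2 + alpha * w
    y1 = bc.y1 - alpha * h
    y2 = bc.y2 + alpha * h
    if image_shape is not None:
        height, width = image_shape
        x1 = max(0.0, x1)
        y1 = max(0.0, y1)
        x2 = min(float(width - 1), x2)
        y2 = min(float(height - 1), y2)
    return BoundingBox(x1=x1, x2=x2, y1=y1, y2=y2)


def shoelace_area(contour: Sequence[Sequence[float]]) -> float:
    """Polygon area by the shoelace formula, ``0.5 * |sum(x_i*y_{i+1} - y_i*x_{i+1})|``.

    The contour is closed implicitly (last vertex connects to the first).
    A zero area (collinear vertices) is returned as 0.0 with a warning;
    fewer than 3 vertices raises :class:`DegenerateContourError`.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateContourError(
            f"contour needs >= 3 (x, y) vertices, got shape {pts.shape}"
        )
    x = pts[:, 0]
    y = pts[:, 1]
    area = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1))))
    if area == 0.0:
        logger.warning("degenerate contour with zero shoelace area")
    return area


# -- exact polygon moments -------------------------------------------------
#
# Raw geometric moments m_pq = integral of x^p y^q over the polygon interior,
# evaluated edge by edge with Green's theorem.  These are the continuous-domain
# moments of the filled region, so Hu invariants derived from them are exactly
# translation/rotation/scale invariant for congruent polygons.


def _polygon_raw_moments(pts: np.ndarray) -> dict[tuple[int, int], float]:
    x = pts[:, 0]
    y = pts[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    a = x * yn - xn * y  # signed cross term per edge

    m = {
        (0, 0): np.sum(a) / 2.0,
        (1, 0): np.sum(a * (x + xn)) / 6.0,
        (0, 1): np.sum(a * (y + yn)) / 6.0,
        (2, 0): np.sum(a * (x * x + x * xn + xn * xn)) / 12.0,
        (0, 2): np.sum(a * (y * y + y * yn + yn * yn)) / 12.0,
        (1, 1): np.sum(a * (2 * x * y + x * yn + xn * y + 2 * xn * yn)) / 24.0,
        (3, 0): np.sum(a * (x**3 + x * x * xn + x * xn * xn + xn**3)) / 20.0,
        (0, 3): np.sum(a * (y**3 + y * y * yn + y * yn * yn + yn**3)) / 20.0,
        (2, 1): np.sum(
            a
            * (
                3 * x * x * y
                + 2 * x * xn * y
                + xn * xn * y
                + x * x * yn
                + 2 * x * xn * yn
                + 3 * xn * xn * yn
            )
        )
        / 60.0,
        (1, 2): np.sum(
            a
            * (
                3 * y * y * x
                + 2 * y * yn * x
                + yn * yn * x
                + y * y * xn
                + 2 * y * yn * xn
                + 3 * yn * yn * xn
            )
        )
        / 60.0,
    }
    if m[(0, 0)] < 0:  # clockwise contour: flip orientation
        m = {k: -v for k, v in m.items()}
    return {k: float(v) for k, v in m.items()}


def polygon_hu_moments(contour: Sequence[Sequence[float]]) -> np.ndarray:
    """The seven Hu shape invariants of a polygon's filled interior (raw values)."""
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateContourError("contour needs >= 3 (x, y) vertices")
    m = _polygon_raw_moments(pts)
    m00 = m[(0, 0)]
    if m00 <= 0.0:
        raise DegenerateContourError("zero-area contour has no shape moments")
    xb = m[(1, 0)] / m00
    yb = m[(0, 1)] / m00

    mu20 = m[(2, 0)] - xb * m[(1, 0)]
    mu02 = m[(0, 2)] - yb * m[(0, 1)]
    mu11 = m[(1, 1)] - xb * m[(0, 1)]
    mu30 = m[(3, 0)] - 3 * xb * m[(2, 0)] + 2 * xb * xb * m[(1, 0)]
    mu03 = m[(0, 3)] - 3 * yb * m[(0, 2)] + 2 * yb * yb * m[(0, 1)]
    mu21 = m[(2, 1)] - 2 * xb * m[(1, 1)] - yb * m[(2, 0)] + 2 * xb * xb * m[(0, 1)]
    mu12 = m[(1, 2)] - 2 * yb * m[(1, 1)] - xb * m[(0, 2)] + 2 * yb * yb * m[(1, 0)]

    def nu(mu: float, p: int, q: int) -> float:
        return mu / m00 ** (1 + (p + q) / 2.0)

    n20 = nu(mu20, 2, 0)
    n02 = nu(mu02, 0, 2)
    n11 = nu(mu11, 1, 1)
    n30 = nu(mu30, 3, 0)
    n03 = nu(mu03, 0, 3)
    n21 = nu(mu21, 2, 1)
    n12 = nu(mu12, 1, 2)

    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    h7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7], dtype=float)


def hu_log_transform(hu: np.ndarray) -> np.ndarray:
    """``sign(h) * log10(|h|)`` per moment; exact zeros stay zero (skipped downstream)."""
    hu = np.asarray(hu, dtype=float)
    out = np.zeros_like(hu)
    nz = hu != 0.0
    out[nz] = np.sign(hu[nz]) * np.log10(np.abs(hu[nz]))
    return out


def compute_hu(contour: Sequence[Sequence[float]], transform: str = "log") -> np.ndarray:
    """Hu moments of a contour, optionally log-transformed (the default)."""
    hu = polygon_hu_moments(contour)
    if transform == "log":
        return hu_log_transform(hu)
    if transform == "raw":
        return hu
    raise ValueError(f"unknown hu transform {transform!r} (expected 'log' or 'raw')")


@dataclass(frozen=True)
class CellInstance:
    """One segmented cell in one frame.

    ``contour`` is an ordered (n, 2) array of (x, y) vertices; ``pixels`` is
    the rasterized filled region as a frozenset of (row, col) pairs, used for
    IoU and overlap tests.
    """

    frame: int
    instance_id: int
    contour: np.ndarray = field(repr=False)
    centroid: tuple[float, float]
    area: float
    bbox: BoundingBox
    hu: np.ndarray = field(repr=False)
    pixels: frozenset = field(repr=False)
    intensity_mean: Optional[float] = None
    intensity_var: Optional[float] = None
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise DegenerateContourError(
                f"instance {self.instance_id} in frame {self.frame} has area {self.area}"
            )
        if len(self.hu) != 7:
            raise ValueError("hu must have exactly 7 entries")

    def with_class(self, label: Optional[str]) -> "CellInstance":
        return replace(self, class_label=label)

    def with_frame(self, frame: int) -> "CellInstance":
        return replace(self, frame=frame)

    @property
    def key(self) -> tuple[int, int]:
        """(frame, instance_id) — unique detection key within a movie."""
        return (self.frame, self.instance_id)


@dataclass
class FrameSegmentation:
    """All segmented instances of a single frame."""

    frame: int
    instances: list[CellInstance]
    image_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        ids = [c.instance_id for c in self.instances]
        if len(ids) != len(set(ids)):
            raise FormatError(f"duplicate instance ids in frame {self.frame}")
        for c in self.instances:
            if c.frame != self.frame:
                raise FormatError(
                    f"instance {c.instance_id} carries frame {c.frame}, expected {self.frame}"
                )


def _contour_from_pixels(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Outer boundary polygon (x, y vertices) of a pixel set via marching squares."""
    r0, c0 = int(rows.min()), int(cols.min())
    h = int(rows.max()) - r0 + 1
    w = int(cols.max()) - c0 + 1
    img = np.zeros((h + 2, w + 2), dtype=float)
    img[rows - r0 + 1, cols - c0 + 1] = 1.0
    contours = _skmeasure.find_contours(img, 0.5)
    if not contours:  # pragma: no cover - a nonempty pixel set always yields one
        raise DegenerateContourError("no contour found for pixel set")
    boundary = max(contours, key=len)
    # (row, col) -> (x, y), undo the 1-pixel pad
    xy = np.column_stack([boundary[:, 1] + c0 - 1, boundary[:, 0] + r0 - 1])
    # marching squares closes the loop: drop the duplicated final vertex
    if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def _largest_component(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = int(rows.min()), int(cols.min())
    img = np.zeros((int(rows.max()) - r0 + 1, int(cols.max()) - c0 + 1), dtype=bool)
    img[rows - r0, cols - c0] = True
    lab, n = _skmeasure.label(img, return_num=True, connectivity=2)
    if n > 1:
        logger.warning("label split into %d connected components; keeping largest", n)
        sizes = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        rr, cc = np.nonzero(lab == keep)
        return rr + r0, cc + c0
    return rows, cols


def _instance_from_pixels(
    rows: np.ndarray,
    cols: np.ndarray,
    frame: int,
    instance_id: int,
    intensity_image: Optional[np.ndarray] = None,
    class_label: Optional[str] = None,
    hu_transform: str = "log",
) -> CellInstance:
    rows, cols = _largest_component(rows, cols)
    contour = _contour_from_pixels(rows, cols)
    centroid = (float(cols.mean()), float(rows.mean()))
    # exclusive max bounds so 1-pixel-thin labels still form a valid box
    bbox = BoundingBox(
        x1=float(cols.min()),
        x2=float(cols.max()) + 1.0,
        y1=float(rows.min()),
        y2=float(rows.max()) + 1.0,
    )
    imean = ivar = None
    if intensity_image is not None:
        vals = np.asarray(intensity_image)[rows, cols].astype(float)
        imean = float(vals.mean())
        ivar = float(vals.var())
    return CellInstance(
        frame=frame,
        instance_id=instance_id,
        contour=contour,
        centroid=centroid,
        area=float(len(rows)),
        bbox=bbox,
        hu=compute_hu(contour, hu_transform),
        pixels=frozenset(zip(rows.tolist(), cols.tolist())),
        intensity_mean=imean,
        intensity_var=ivar,
        class_label=class_label,
    )


def extract_instances(
    label_mask: np.ndarray,
    frame: int,
    intensity_image: Optional[np.ndarray] = None,
    class_map: Optional[Mapping[int, str]] = None,
    hu_transform: str = "log",
) -> FrameSegmentation:
    """Build one :class:`CellInstance` per positive label of a 2D label mask.

    Parameters
    ----------
    label_mask:
        2D array of nonnegative integers; 0 is background, each positive
        label is one cell.  Labels above 255 are accepted.
    frame:
        Frame index stored on the instances.
    intensity_image:
        Optional same-shaped image for per-cell intensity mean/variance.
    class_map:
        Optional mapping label -> class string.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise FormatError(f"label mask must be 2D, got {mask.ndim}D")
    if not np.issubdtype(mask.dtype, np.integer):
        if np.issubdtype(mask.dtype, np.floating) and np.all(mask == np.floor(mask)):
            mask = mask.astype(np.int64)
        else:
            raise FormatError(f"label mask must be integer-typed, got {mask.dtype}")
    if mask.size and mask.min() < 0:
        raise FormatError("label mask contains negative labels")
    if intensity_image is not None and np.asarray(intensity_image).shape != mask.shape:
        raise FormatError("intensity image shape does not match label mask")

    instances = []
    for label in np.unique(mask):
        if label == 0:
            continue
        rows, cols = np.nonzero(mask == label)
        cls = class_map.get(int(label)) if class_map else None
        instances.append(
            _instance_from_pixels(
                rows,
                cols,
                frame=frame,
                instance_id=int(label),
                intensity_image=intensity_image,
                class_label=cls,
                hu_transform=hu_transform,
            )
        )
    instances.sort(key=lambda c: c.instance_id)
    return FrameSegmentation(frame=frame, instances=instances, image_shape=mask.shape)


def instance_from_polygon(
    xs: Sequence[float],
    ys: Sequence[float],
    frame: int,
    instance_id: int,
    class_label: Optional[str] = None,
    hu_transform: str = "log",
) -> CellInstance:
    """Build a :class:`CellInstance` from polygon vertices (e.g. a VIA region).

    The area is the shoelace area of the polygon; the pixel raster used for
    IoU is the polygon's filled rasterization.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise FormatError("all_points_x and all_points_y lengths differ")
    if xs.size < 3:
        raise DegenerateContourError("polygon needs >= 3 vertices")
    contour = np.column_stack([xs, ys])
    area = shoelace_area(contour)
    if area == 0.0:
        raise DegenerateContourError("zero-area polygon")
    rr, cc = _draw.polygon(ys, xs)
    if rr.size == 0:  # thin sliver: fall back to perimeter pixels
        rr, cc = _draw.polygon_perimeter(
            np.round(ys).astype(int), np.round(xs).astype(int)
        )
    m = _polygon_raw_moments(contour)
    centroid = (m[(1, 0)] / m[(0, 0)], m[(0, 1)] / m[(0, 0)])
    bbox = BoundingBox(
        x1=float(xs.min()), x2=float(xs.max()), y1=float(ys.min()), y2=float(ys.max())
    )
    return CellInstance(
        frame=frame,
        instance_id=instance_id,
        contour=contour,
        centroid=centroid,
        area=area,
        bbox=bbox,
        hu=compute_hu(contour, hu_transform),
        pixels=frozenset(zip(rr.tolist(), cc.tolist())),
        class_label=class_label,
    )


def mask_iou(a: CellInstance, b: CellInstance) -> float:
    """Intersection-over-union of the rasterized filled regions of two cells."""
    if not a.pixels or not b.pixels:
        raise DegenerateContourError("IoU of a zero-area instance is undefined")
    if not a.bbox.intersects(b.bbox):
        return 0.0
    inter = len(a.pixels & b.pixels)
    if inter == 0:
        return 0.0
    union = len(a.pixels | b.pixels)
    return inter / union
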