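"""Five-component similarity index for resolving contested frame-to-frame links.

The total is the plain (optionally weighted) sum of:

* ``iou``   — rasterized intersection-over-union, in [0, 1];
* ``dis``   — inverse centroid distance, ``1 / (1e-5 + d)``, capped at 1e5;
* ``sps``   — Hu-moment shape distance, ``sum |1/m_n^i - 1/m_n^j|`` (0 = congruent);
* ``sas``   — area ratio, ``min(area) / max(area)``, in (0, 1];
* ``delta`` — intensity term, the sum of min/max ratios of means and of
  variances; 0 when either side carries no intensity data.

Note that ``sps`` is a *dissimilarity* (0 for identical shapes) while the
default combination simply adds it with weight +1, exactly as the printed
formula does; the per-component weights are exposed so users may negate it.
No cross-component normalization is applied, so ``dis`` dominates at short
range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DegenerateContourError
from .features import CellInstance, mask_iou

logger = logging.getLogger(__name__)

#: Cap of the inverse-distance term (coincident centroids).
DIS_CAP = 1.0 / 1e-5

#: Default component weights (iou, dis, sps, sas, delta).
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0, 1.0)

#: Raw Hu values with magnitude below this are treated as exact zeros and the
#: corresponding sps term is skipped (symmetric shapes produce analytic zeros
#: that float arithmetic renders as ~1e-17 noise).
_HU_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class SimilarityBreakdown:
    """The five components and their weighted total."""

    iou: float
    dis: float
    sps: float
    sas: float
    delta: float
    total: float


def dis(ci: CellInstance, cj: CellInstance) -> float:
    """Inverse centroid distance ``1 / (1e-5 + euclidean distance)``."""
    d = math.hypot(ci.centroid[0] - cj.centroid[0], ci.centroid[1] - cj.centroid[1])
    return 1.0 / (1e-5 + d)


def sps(ci: CellInstance, cj: CellInstance) -> float:
    """Hu-moment shape distance ``sum_n |1/m_n^i - 1/m_n^j|``.

    Terms where either side's moment is (numerically) zero are skipped.
    """
    total = 0.0
    for n, (mi, mj) in enumerate(zip(ci.hu, cj.hu), start=1):
        if abs(mi) < _HU_ZERO_TOL or abs(mj) < _HU_ZERO_TOL:
            logger.debug("sps: skipping zero moment m_%d", n)
            continue
        total += abs(1.0 / mi - 1.0 / mj)
    return total


def sas(ci: CellInstance, cj: CellInstance) -> float:
    """Area similarity ``min(areas) / max(areas)`` in (0, 1]."""
    if ci.area <= 0 or cj.area <= 0:
        raise DegenerateContourError("area similarity of a zero-area instance")
    return min(ci.area, cj.area) / max(ci.area, cj.area)


def delta_intensity(ci: CellInstance, cj: CellInstance) -> float:
    """Intensity term: min/max ratio of means plus min/max ratio of variances.

    Returns 0 when either instance carries no intensity statistics, so the
    term vanishes cleanly for label-mask-only inputs.
    """
    if ci.intensity_mean is None or cj.intensity_mean is None:
        return 0.0
    total = 0.0
    means = sorted([ci.intensity_mean, cj.intensity_mean])
    if means[1] > 0:
        total += means[0] / means[1]
    if ci.intensity_var is not None and cj.intensity_var is not None:
        variances = sorted([ci.intensity_var, cj.intensity_var])
        if variances[1] > 0:
            total += variances[0] / variances[1]
    return total


def similarity_index(
    ci: CellInstance,
    cj: CellInstance,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> SimilarityBreakdown:
    """Full similarity breakdown between two instances.

    ``weights`` are applied in the order (iou, dis, sps, sas, delta);
    the default all-ones weights reproduce the plain sum.
    """
    if len(weights) != 5:
        raise ValueError("weights must have 5 entries (iou, dis, sps, sas, delta)")
    components = (
        mask_iou(ci, cj),
        dis(ci, cj),
        sps(ci, cj),
        sas(ci, cj),
        delta_intensity(ci, cj),
    )
    total = sum(w * c for w, c in zip(weights, components))
    return SimilarityBreakdown(*components, total=float(total))
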