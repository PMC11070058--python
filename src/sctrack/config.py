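"""Tracker configuration with the published defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .errors import ConfigurationError


@dataclass
class TrackerConfig:
    """All tunable tracking parameters.

    Defaults follow the published tool defaults: bounding-box expansion
    coefficient 1.5, a 5-frame cache search, 3-frame fragment linking,
    10-frame minimum track span, 1.3x mother/daughter size ratio, 50-frame
    division cooldown, and a 9-frame / 60% class-smoothing rule.
    """

    alpha: float = 1.5  # available-range (bounding-box expansion) coefficient
    cache_depth: int = 5
    fragment_link_gap: int = 3
    min_track_span: int = 10
    division_size_ratio: float = 1.3
    division_cooldown: int = 50
    tcs_window: int = 9
    tcs_threshold: float = 0.60
    tcs_min_window: int = 3  # no class switch decided on fewer remaining nodes
    weights: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    use_class_for_division: str = "auto"  # "auto" | "on" | "off"
    hu_transform: str = "log"  # "log" | "raw"
    iou_min: float = 0.5  # detection-matching threshold (evaluation only)
    division_frame_tolerance: int = 1  # evaluation only
    via_class_key: str = "phase"
    per_class_tcs_thresholds: Optional[dict] = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if self.cache_depth < 1:
            raise ConfigurationError("cache_depth must be >= 1")
        if self.fragment_link_gap < 1:
            raise ConfigurationError("fragment_link_gap must be >= 1")
        if self.min_track_span < 1:
            raise ConfigurationError("min_track_span must be >= 1")
        if self.division_size_ratio < 1.0:
            raise ConfigurationError("division_size_ratio must be >= 1")
        if self.division_cooldown < 0:
            raise ConfigurationError("division_cooldown must be >= 0")
        if self.tcs_window < 1:
            raise ConfigurationError("tcs_window must be >= 1")
        if not (0.0 <= self.tcs_threshold <= 1.0):
            raise ConfigurationError("tcs_threshold must be in [0, 1]")
        if len(tuple(self.weights)) != 5:
            raise ConfigurationError("weights must have 5 entries")
        if self.use_class_for_division not in ("auto", "on", "off"):
            raise ConfigurationError("use_class_for_division must be auto|on|off")
        if self.hu_transform not in ("log", "raw"):
            raise ConfigurationError("hu_transform must be log|raw")
        self.weights = tuple(float(w) for w in self.weights)

    def to_dict(self) -> dict:
        return asdict(self)
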