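"""Screen configuration shared across funnel stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .proteome import DEFAULT_BACKGROUND, DEFAULT_CV_TOLERANCE
from .reduction import Convention

__all__ = ["ScreenConfig"]


@dataclass
class ScreenConfig:
    """All tunable thresholds of the screening funnel.

    ``r_threshold`` (default 0.7) and ``min_conditions`` of
    ``n_conditions`` (default 3 of 4) define the correlation selection
    rule; selection uses signed r unless ``use_absolute_r``.
    ``background_threshold`` is the log2 detection floor, ``p_max`` the
    SNP-association cut, and ``convention`` the sign convention of the
    percent statistic.  ``panel`` optionally restricts the strain panel.
    """

    r_threshold: float = 0.7
    min_conditions: int = 3
    n_conditions: int = 4
    use_absolute_r: bool = False
    background_threshold: float = DEFAULT_BACKGROUND
    cv_tolerance: float = DEFAULT_CV_TOLERANCE
    p_max: float = 0.05
    convention: Convention = Convention.REMAINING
    panel: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError(f"r_threshold must be in (0, 1), got {self.r_threshold}")
        if self.min_conditions > self.n_conditions:
            raise ValueError("min_conditions cannot exceed n_conditions")
        if self.min_conditions < 1:
            raise ValueError("min_conditions must be at least 1")
        if not (0.0 < self.p_max < 1.0):
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")
        self.convention = Convention(self.convention)
        if self.panel is not None:
            self.panel = tuple(self.panel)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["convention"] = self.convention.value
        d["panel"] = list(self.panel) if self.panel is not None else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        """Load from a flat key-value YAML file; absent keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
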