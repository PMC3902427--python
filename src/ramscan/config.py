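"""Pipeline configuration.

Every tuning constant of the window/test/filter chain lives here with the
defaults the analysis is defined by: 100 bp windows on a 50 bp shift, the
≥10-reads-in-25%-of-samples coverage floor, p < 0.05 calling, half-of-group
(min 2) per-sample support, the 500 bp adjacency stretch, ±1.5 kb promoters,
0–2 kb shores / 2–4 kb shelves, and the 5-fold heatmap filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

COMPARISONS = ("Ctr_vs_UG", "Ctr_vs_MG", "UG_vs_MG")
GROUPS = ("Ctr", "UG", "MG")
COMPARISON_GROUPS = {
    "Ctr_vs_UG": ("Ctr", "UG"),
    "Ctr_vs_MG": ("Ctr", "MG"),
    "UG_vs_MG": ("UG", "MG"),
}


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class PipelineConfig:
    window_size: int = 100          # bp per window
    window_shift: int = 50          # bp between successive window starts
    min_reads: int = 10             # coverage floor per window per sample
    min_sample_fraction: float = 0.25   # fraction of samples that must reach the floor
    alpha: float = 0.05             # per-window p-value gate
    support_fraction: float = 0.5   # fraction of each group (min 2) that must support
    adjacency_stretch: int = 500    # bp stretch within which two windows corroborate
    promoter_flank: int = 1500      # bp either side of a TSS
    shore_extent: int = 2000        # bp of CGI flank called shore
    shelf_extent: int = 2000        # bp beyond the shore called shelf
    heatmap_fold: int = 5           # fold change admitting a window to the heatmap
    read_extension: int = 0         # optional 3'-ward read extension before anchoring
    normalization: str = "raw"      # 'raw' totals or 'tmm' trimmed-mean adjustment

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.window_shift <= 0 or self.window_size <= 0:
            errs.append("window_size and window_shift must be positive")
        elif self.window_size % self.window_shift != 0:
            errs.append("window_shift must divide window_size")
        if not 0 < self.alpha < 1:
            errs.append("alpha must lie in (0, 1)")
        if not 0 < self.min_sample_fraction <= 1:
            errs.append("min_sample_fraction must lie in (0, 1]")
        if not 0 < self.support_fraction <= 1:
            errs.append("support_fraction must lie in (0, 1]")
        for name in ("min_reads", "adjacency_stretch", "promoter_flank",
                     "shore_extent", "shelf_extent", "heatmap_fold"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if self.adjacency_stretch < self.window_size:
            errs.append("adjacency_stretch must be at least window_size")
        if self.read_extension < 0:
            errs.append("read_extension must be non-negative")
        if self.normalization not in ("raw", "tmm"):
            errs.append("normalization must be 'raw' or 'tmm'")
        if errs:
            raise ConfigError("; ".join(errs))

    @property
    def adjacency_max_gap(self) -> int:
        """Max |Δstart| so that both windows fit inside one adjacency stretch."""
        return self.adjacency_stretch - self.window_size

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = sorted(set(d) - known)
        if bad:
            raise ConfigError(f"unknown configuration fields: {', '.join(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config fields")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
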