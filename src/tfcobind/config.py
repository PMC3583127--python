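"""Structured pipeline configuration (YAML) with upfront validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from tfcobind.pairscan import DEFAULT_GRID


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, validated before any work."""

    # input/output paths
    promoters: Optional[str] = None
    motifs: Optional[str] = None
    tissues: Optional[str] = None
    ppi: Optional[str] = None
    affinity_tsv: Optional[str] = None  # precomputed gene x factor matrix
    similarity_tsv: Optional[str] = None  # precomputed similarity matrix
    outdir: str = "tfcobind_out"
    # affinity model
    lam: float = 0.7
    r0: Optional[float] = None
    pseudocount: float = 1.0
    background: Optional[list[float]] = None
    # pair scan grid
    grid: list[int] = field(default_factory=lambda: list(DEFAULT_GRID))
    # similarity
    hit_p: float = 0.01
    similarity_cutoff: float = 4.0
    # tissue test
    top_l: int = 1000
    # calling thresholds (log10 p) per context kind
    threshold_global: float = -20.0
    threshold_tissue: float = -6.0
    threshold_cell_line: float = -11.0
    cell_line_contexts: list[str] = field(default_factory=list)
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        grid = list(self.grid)
        if not grid or any(g <= 0 for g in grid):
            raise ValueError("grid values must be positive")
        if sorted(set(grid)) != grid:
            raise ValueError("grid values must be strictly increasing")
        for name in ("threshold_global", "threshold_tissue", "threshold_cell_line"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be a log10 p-value <= 0")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if not 0 < self.hit_p < 0.5:
            raise ValueError("hit_p must lie in (0, 0.5)")
        if self.top_l <= 0:
            raise ValueError("top_l must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def threshold_for(self, context: str) -> float:
        if context == "global":
            return self.threshold_global
        if context in self.cell_line_contexts:
            return self.threshold_cell_line
        return self.threshold_tissue

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name
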