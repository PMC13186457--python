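"""Run configuration: YAML file plus CLI overrides, validated up front."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    counts: str = ""
    annotations: str = ""
    lr_db: str = ""  # empty -> packaged demo table
    outdir: str = "rankcomm_out"
    counts_format: str = "auto"
    transpose: bool = False
    min_genes: int = 200
    n_bins: int = 20
    min_cells: int = 10
    min_frac: float = 0.1
    gof_alpha: float = 0.05
    require_gof: bool = True
    n_perm: int = 1000
    seed: int = 0
    score_mode: str = "product"
    tmm_groupby: str | None = None
    compute_weights: bool = False
    render_heatmaps: bool = False
    overrides: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if not self.counts:
            raise ConfigError("config must set 'counts'")
        if not self.annotations:
            raise ConfigError("config must set 'annotations'")
        if self.min_genes < 1:
            raise ConfigError("min_genes must be >= 1")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        if self.min_cells < 1:
            raise ConfigError("min_cells must be >= 1")
        if not (0 <= self.min_frac <= 1):
            raise ConfigError("min_frac must be in [0, 1]")
        if not (0 < self.gof_alpha < 1):
            raise ConfigError("gof_alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.score_mode not in ("product", "dgbd_weighted"):
            raise ConfigError(f"unknown score_mode {self.score_mode!r}")
        if self.tmm_groupby not in (None, "cell_type"):
            raise ConfigError(f"unknown tmm_groupby {self.tmm_groupby!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Load with precedence: CLI overrides > file values > defaults."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file does not exist: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls) if f.name != "overrides"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        cfg = cls(**merged)
        cfg.overrides = {k: v for k, v in overrides.items() if v is not None}
        cfg.validate()
        return cfg

    def non_default(self) -> dict:
        """Parameters differing from defaults (for the run log)."""
        default = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "overrides" and getattr(self, f.name) != getattr(default, f.name)
        }
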