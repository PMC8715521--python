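"""Run configuration for sLTP learning.

Defaults follow the published parameter setting for full-cohort training:
25 mm ROIs at secondary-lobule scale, SURS sampling with a random shift of
up to ``beta1`` mm and ``beta2`` samples per stack, a 40-texton codebook of
3x3x3 patches, a 36-bin (r, theta, phi) spatial partition, 100 initial LTPs,
a spatial-regularization grid over lambda in [0, 2] tuned at a 1% texture
homogeneity loss, and a 0.5 replacement-ratio edge threshold for merging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Optional

import yaml

from .exceptions import ConfigError


@dataclass
class RunConfig:
    # ROI sampling
    roi_edge_mm: float = 25.0       # cube edge of a region of interest
    beta1: float = 25.0             # max uniform random shift per axis, mm
    beta2: int = 3                  # sampled candidates per SURS stack
    # texture features
    n_textons: int = 40
    texton_size: int = 3            # patch edge, voxels
    max_codebook_patches: int = 100_000
    # spatial features: r x theta x phi partition (36 sub-regions)
    n_r_bins: int = 3
    n_theta_bins: int = 4
    n_phi_bins: int = 3
    # LTP learning
    n_ltp: int = 100
    lambda_min: float = 0.0
    lambda_max: float = 2.0
    lambda_steps: int = 51
    l_t: float = 1.0                # acceptable texture homogeneity loss, percent
    # merging
    edge_threshold: float = 0.5
    # visualization
    n_r: int = 60                   # radial positions for projections / density plots
    n_isov: int = 5000              # ROIs sampled in the outermost radial bin
    # emphysema gating
    emph_threshold_hu: float = -950.0
    gate_percent: float = 1.0
    # bookkeeping
    seed: int = 0
    phantom: Optional[dict] = None  # optional inline phantom spec overrides

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.roi_edge_mm <= 0:
            raise ConfigError("roi_edge_mm must be positive")
        if self.beta1 < 0:
            raise ConfigError("beta1 must be >= 0")
        if self.beta2 < 1:
            raise ConfigError("beta2 must be >= 1")
        if self.n_textons < 2 or self.texton_size < 1:
            raise ConfigError("texton parameters out of range")
        if self.n_r_bins < 1 or self.n_theta_bins < 1 or self.n_phi_bins < 1:
            raise ConfigError("spatial bin counts must be >= 1")
        if self.n_ltp < 1:
            raise ConfigError("n_ltp must be >= 1")
        if not (0 <= self.lambda_min <= self.lambda_max):
            raise ConfigError("lambda grid must satisfy 0 <= min <= max")
        if self.lambda_steps < 1:
            raise ConfigError("lambda_steps must be >= 1")
        if self.l_t <= 0:
            raise ConfigError("l_t must be > 0")
        if not (0 <= self.edge_threshold <= 1):
            raise ConfigError("edge_threshold must be in [0, 1]")
        if self.n_r < 1 or self.n_isov < 1:
            raise ConfigError("visualization sizes must be >= 1")

    @property
    def n_subregions(self) -> int:
        return self.n_r_bins * self.n_theta_bins * self.n_phi_bins

    @property
    def lambda_grid(self) -> list[float]:
        import numpy as np

        return list(np.linspace(self.lambda_min, self.lambda_max, self.lambda_steps))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return str(path)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
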