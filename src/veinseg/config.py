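"""Run configuration: every tunable of the pipeline in one validated record.

The configuration is organised in four sections mirroring the pipeline
stages (``gabor``, ``fusion``, ``segmentation``, ``sampling``) plus a
top-level ``seed``.  Defaults reproduce the published operating point:
256x256 padded images tiled into 16x16-pixel blocks, a 5-scale (steps of
2 in window width) x 8-orientation Gabor bank, a 5-component diagonal
GMM per label, an 8-connected smoothness neighbourhood, and a 100x200
fingertip collection box.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["GaborConfig", "FusionConfig", "SegmentationConfig",
           "SamplingConfig", "RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file or override is invalid."""


@dataclass
class GaborConfig:
    target_size: int = 256        # padded square side, pixels
    block_size: int = 16          # tile side, pixels (16x16 blocks at 256)
    w_min: float = 6.0            # clamp for the adaptive window width
    w_max: float = 32.0
    n_scales: int = 5
    scale_step: float = 2.0       # widths = center + step*{-2,-1,0,1,2}
    n_orientations: int = 8
    gradient_operator: str = "sobel"   # 'sobel' | 'prewitt'
    truncate_sigmas: float = 3.0  # kernel support half-width in sigmas

    def validate(self) -> None:
        if self.block_size <= 0 or self.target_size % self.block_size:
            raise ConfigError(
                f"block_size {self.block_size} must divide target_size "
                f"{self.target_size}")
        if not (0 < self.w_min <= self.w_max):
            raise ConfigError("need 0 < w_min <= w_max")
        if self.w_min - (self.n_scales // 2) * self.scale_step < 2:
            raise ConfigError("smallest scale width would fall below 2 px")
        if self.gradient_operator not in ("sobel", "prewitt"):
            raise ConfigError(
                f"unknown gradient_operator {self.gradient_operator!r}")


@dataclass
class FusionConfig:
    # orientation s gets bit weight 2**(s-1): LSB-first code assembly
    lsb_first: bool = True


@dataclass
class SegmentationConfig:
    n_components: int = 5         # GMM components per label (K)
    beta: float = 0.1             # smoothness weight in the MRF energy
    c_noise: float = math.pi      # additive anti-noise constant in phi
    neighborhood: int = 8         # 4- or 8-connected smoothness graph
    variance_floor: float = 1e-3
    likelihood_floor: float = 1e-12
    eta_max: float = 1e6          # eta fallback when all distances vanish
    tol: float = 1e-2             # |delta KL| convergence threshold
    max_iters: int = 10
    kl_samples: int = 2000        # Monte-Carlo draws for the KL estimate
    init_method: str = "intensity_otsu"  # 'intensity_otsu' | 'fused_otsu' | 'markers'
    # locality preserving projection of the 5 fused-scale features
    lpp_dim: int = 4
    lpp_neighbors: int = 7
    lpp_subsample: int = 5000
    lpp_identity: bool = False    # fallback: raw Euclidean feature distance
    kmeans_subsample: int = 20000

    def validate(self) -> None:
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.neighborhood not in (4, 8):
            raise ConfigError("neighborhood must be 4 or 8")
        if self.init_method not in ("fused_otsu", "intensity_otsu", "markers"):
            raise ConfigError(f"unknown init_method {self.init_method!r}")
        if self.beta < 0 or self.c_noise < 0:
            raise ConfigError("beta and c_noise must be non-negative")


@dataclass
class SamplingConfig:
    box_rows: int = 100           # collection-box extent along the finger axis
    box_cols: int = 200           # extent across the finger
    harris_k: float = 0.04
    harris_sigma: float = 1.5
    threshold_frac: float = 0.01
    nms_radius: int = 5

    def validate(self) -> None:
        if self.box_rows <= 0 or self.box_cols <= 0:
            raise ConfigError("collection box dimensions must be positive")
        if not (0 < self.threshold_frac < 1):
            raise ConfigError("threshold_frac must lie in (0, 1)")


@dataclass
class RunConfig:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.gabor.validate()
        self.segmentation.validate()
        self.sampling.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        """Build a config from a (possibly partial) nested mapping.

        Unknown section or key names are rejected so that typos in a YAML
        file fail loudly rather than silently keeping a default.
        """
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, value in data.items():
            if section not in sections:
                raise ConfigError(f"unknown config section {section!r}")
            if section == "seed":
                cfg.seed = int(value)
                continue
            sub = getattr(cfg, section)
            valid = {f.name for f in dataclasses.fields(sub)}
            if not isinstance(value, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            for key, v in value.items():
                if key not in valid:
                    raise ConfigError(
                        f"unknown key {key!r} in section {section!r}")
                setattr(sub, key, type(getattr(sub, key))(v))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)
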