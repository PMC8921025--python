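"""Configuration blocks for acquisition, quantification, ROI and statistics stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "AcquisitionConfig",
    "KineticsConfig",
    "ROIConfig",
    "StatsConfig",
    "PipelineConfig",
]


@dataclass
class AcquisitionConfig:
    """Acquisition geometry and timing of the simulated dynamic series.

    Defaults mirror a time-resolved thoracic protocol: 1.5 s frame spacing,
    2 mm isotropic voxels and five pre-contrast baseline frames.
    """

    frame_interval: float = 1.5   # s
    voxel_size: float = 2.0       # mm, isotropic
    n_baseline: int = 5
    n_frames: int = 40
    noise_sigma: float = 1.0      # additive Gaussian signal noise, a.u.
    baseline_signal: float = 100.0  # S0, a.u.
    enhancement_gain: float = 1.0   # k in S = S0 * (1 + k * C)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if self.n_frames <= self.n_baseline:
            raise ValueError("n_frames must exceed n_baseline")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def frame_times(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class KineticsConfig:
    """Deconvolution settings.

    regularization_fraction : singular values below this fraction of the
        largest are zeroed before pseudo-inversion (truncated SVD).
    conversion : "subtract" uses C = S - S0; "relative" uses (S - S0)/S0.
        Both are equivalent for quantification when S0 is spatially uniform,
        because PBF and PBV are ratios against the arterial curve.
    mtt_mode : "central_volume" derives MTT as 60*PBV/PBF (internally
        consistent maps); "residue_area" integrates the deconvolved residue.
    """

    regularization_fraction: float = 0.15
    conversion: str = "subtract"
    mtt_mode: str = "central_volume"

    def __post_init__(self) -> None:
        if not (0.0 <= self.regularization_fraction < 1.0):
            raise ValueError("regularization_fraction must be in [0, 1)")
        if self.conversion not in ("subtract", "relative"):
            raise ValueError(f"unknown conversion mode {self.conversion!r}")
        if self.mtt_mode not in ("central_volume", "residue_area"):
            raise ValueError(f"unknown mtt mode {self.mtt_mode!r}")


@dataclass
class ROIConfig:
    """ROI refinement settings for macrovessel exclusion."""

    vessel_percentile: float = 99.0
    max_excluded_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 < self.vessel_percentile <= 100.0):
            raise ValueError("vessel_percentile must be in (0, 100]")
        if not (0.0 < self.max_excluded_fraction < 1.0):
            raise ValueError("max_excluded_fraction must be in (0, 1)")


@dataclass
class StatsConfig:
    """Statistical-layer settings.

    Welch's unpaired test is the default (robust to unequal group
    variances); Student's pooled-variance variant is available by flag.
    Spirometric impairment uses the conventional fixed cut-offs:
    obstruction iff Tiffeneau index < 0.70, restriction iff FVC < 80%
    of predicted.
    """

    unpaired_variant: str = "welch"
    alpha: float = 0.05
    tiffeneau_cutoff: float = 0.70
    fvc_pct_cutoff: float = 80.0

    def __post_init__(self) -> None:
        if self.unpaired_variant not in ("welch", "student"):
            raise ValueError(f"unknown unpaired variant {self.unpaired_variant!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Top-level configuration binding all stages of a synthetic run."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    n_cdh: int = 54
    n_control: int = 10
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    render: bool = True

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        for name, sub_cls in (
            ("acquisition", AcquisitionConfig),
            ("kinetics", KineticsConfig),
            ("roi", ROIConfig),
            ("stats", StatsConfig),
        ):
            if name in raw:
                kwargs[name] = sub_cls(**raw[name])
        for name in ("seed", "n_cdh", "n_control", "render"):
            if name in raw:
                kwargs[name] = raw[name]
        if "grid_shape" in raw:
            kwargs["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
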