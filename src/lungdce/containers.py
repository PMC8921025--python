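"""Core in-memory containers shared by the simulation and quantification stages.

Units follow the perfusion-imaging convention throughout: pulmonary blood
flow (PBF) in mL/100 mL/min, pulmonary blood volume (PBV) in mL/100 mL,
mean transit time (MTT) in seconds, lung volume in mL, frame spacing in
seconds and voxel size in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicSeries",
    "ConcentrationSeries",
    "AIFCurve",
    "ResidueEstimate",
    "PerfusionMaps",
    "SideSummary",
    "SubjectRecord",
    "TestResult",
]

_REL_TOL_UNIFORM = 1e-6


@dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced signal S(x, t).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz, n_frames)
        Signal intensity in arbitrary units.
    frame_times : ndarray, shape (n_frames,)
        Frame acquisition times in seconds; must be uniformly spaced.
    voxel_size : float
        Isotropic voxel edge length in mm.
    n_baseline : int
        Number of pre-contrast frames at the start of the series.
    """

    values: np.ndarray
    frame_times: np.ndarray
    voxel_size: float
    n_baseline: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"dynamic series must be 4D, got shape {self.values.shape}"
            )
        if self.values.shape[3] != self.frame_times.size:
            raise ValueError("frame_times length must match the time axis")
        if self.frame_times.size >= 2:
            steps = np.diff(self.frame_times)
            if np.any(steps <= 0):
                raise ValueError("frame_times must be strictly increasing")
            if np.ptp(steps) > _REL_TOL_UNIFORM * steps.mean():
                raise ValueError("frame_times must be uniformly spaced")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if self.n_baseline >= self.frame_times.size:
            raise ValueError("n_baseline must be smaller than n_frames")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def dt(self) -> float:
        """Frame spacing in seconds."""
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass
class ConcentrationSeries:
    """Indicator concentration C(t) for a voxel or an ROI mean, a.u. per frame."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("concentration curve must be a non-empty 1D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def area(self) -> float:
        """Rectangular-rule area dt * sum(C)."""
        return float(self.dt * self.values.sum())


@dataclass
class AIFCurve:
    """Arterial input function C_a(t) from the pulmonary-trunk ROI."""

    values: np.ndarray
    dt: float
    source_roi_size: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("AIF curve must be a non-empty 1D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def area(self) -> float:
        return float(self.dt * self.values.sum())

    @property
    def peak(self) -> float:
        return float(self.values.max())


@dataclass
class ResidueEstimate:
    """Deconvolved flow-scaled residue f*R(t), units 1/s."""

    fr_values: np.ndarray
    dt: float
    regularization_fraction: float

    def __post_init__(self) -> None:
        self.fr_values = np.asarray(self.fr_values, dtype=float)
        if not np.all(np.isfinite(self.fr_values)):
            raise ValueError("residue estimate must be finite")


@dataclass
class PerfusionMaps:
    """Voxelwise PBF/PBV/MTT maps over a mask.

    Values are NaN outside ``valid_mask``; ``n_excluded`` counts in-mask
    voxels dropped because the deconvolution produced a non-positive flow
    or a non-positive tissue area.
    """

    pbf: np.ndarray
    pbv: np.ndarray
    mtt: np.ndarray
    valid_mask: np.ndarray
    voxel_size: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.pbf.shape == self.pbv.shape == self.mtt.shape == self.valid_mask.shape):
            raise ValueError("map shapes must agree")


@dataclass
class SideSummary:
    """Per-lung-side ROI summary: unweighted means and volume from voxel count."""

    subject_id: str
    side_role: str  # "ipsilateral" or "contralateral"
    mean_pbf: float
    mean_pbv: float
    mean_mtt: float
    lung_volume: float  # mL
    n_voxels: int


@dataclass
class SubjectRecord:
    """One subject's per-side summaries plus the ipsi/contra PBF ratio."""

    subject_id: str
    group: str  # "CDH" or "control"
    hernia_side: str | None
    ecmo: bool
    ipsilateral: SideSummary
    contralateral: SideSummary
    pbf_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.contralateral.mean_pbf <= 0:
            raise ValueError("contralateral mean PBF must be positive")
        self.pbf_ratio = self.ipsilateral.mean_pbf / self.contralateral.mean_pbf


@dataclass
class TestResult:
    """Outcome of a classical hypothesis test (two-sided)."""

    statistic: float
    degrees_of_freedom: float
    p_value: float
    test_name: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        """Significance at the conventional two-sided alpha = 0.05."""
        return self.p_value < 0.05
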