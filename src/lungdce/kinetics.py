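"""Voxelwise perfusion quantification by regularized deconvolution.

The tissue curve is modelled as C_t(t) = f * (C_a (*) R)(t), discretized on
the frame grid as a lower-triangular Toeplitz system A fr = c with
A[i, j] = dt * C_a(t_{i-j}). The flow-scaled residue fr = f*R(t) is
recovered by truncated-SVD pseudo-inversion; singular values below a
configurable fraction of the largest are zeroed. Parameters follow the
indicator-dilution readouts:

    PBF = 6000 * max_t fr(t)                [mL/100 mL/min]
    PBV = 100 * area(C_t) / area(C_a)       [mL/100 mL]
    MTT = 60 * PBV / PBF                    [s]  (central volume theorem)
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz

from .config import KineticsConfig
from .containers import AIFCurve, ConcentrationSeries, DynamicSeries, PerfusionMaps, ResidueEstimate

__all__ = [
    "DegenerateAIFError",
    "signal_to_concentration",
    "extract_aif",
    "build_convolution_matrix",
    "deconvolve_tsvd",
    "tsvd_operator",
    "compute_parameters",
    "make_maps",
]

# Singular values below this absolute fraction of sigma_max are always
# treated as zero: pre-arrival AIF frames make the Toeplitz system exactly
# rank-deficient, and inverting numerical zeros is meaningless at any
# requested truncation level.
_RANK_EPS = 1e-12


class DegenerateAIFError(ValueError):
    """All singular values of the convolution operator were suppressed."""


def signal_to_concentration(
    series: DynamicSeries,
    voxel: tuple[int, int, int] | None = None,
    mode: str = "subtract",
) -> ConcentrationSeries:
    """Convert signal to concentration by baseline subtraction.

    C(t) = S(t) - S0 with S0 the mean over the baseline frames (mode
    "subtract"), or (S(t) - S0)/S0 (mode "relative"). With a single voxel
    given, returns that voxel's curve; otherwise the spatial-mean curve of
    the whole grid.
    """
    if voxel is not None:
        s = series.values[voxel]
    else:
        s = series.values.reshape(-1, series.n_frames).mean(axis=0)
    return ConcentrationSeries(_convert(s, series.n_baseline, mode), series.dt)


def _convert(signal: np.ndarray, n_baseline: int, mode: str) -> np.ndarray:
    s0 = signal[..., :n_baseline].mean(axis=-1, keepdims=True)
    if mode == "subtract":
        return signal - s0
    if mode == "relative":
        return (signal - s0) / s0
    raise ValueError(f"unknown conversion mode {mode!r}")


def extract_aif(
    series: DynamicSeries,
    trunk_mask: np.ndarray,
    mode: str = "subtract",
) -> AIFCurve:
    """Arterial input function: unweighted ROI-mean concentration over the
    trunk mask, clipped at zero after baseline subtraction."""
    trunk_mask = np.asarray(trunk_mask, dtype=bool)
    if trunk_mask.shape != series.grid_shape:
        raise ValueError("trunk mask shape does not match the series grid")
    n = int(trunk_mask.sum())
    if n == 0:
        raise ValueError("empty AIF ROI: trunk mask contains no voxels")
    curves = _convert(series.values[trunk_mask], series.n_baseline, mode)
    mean_curve = np.clip(curves.mean(axis=0), 0.0, None)
    return AIFCurve(mean_curve, series.dt, source_roi_size=n)


def build_convolution_matrix(aif: AIFCurve) -> np.ndarray:
    """Lower-triangular Toeplitz operator A[i, j] = dt * C_a(t_{i-j})."""
    ca = aif.values
    if ca.size < 2:
        raise ValueError("AIF must have at least two samples")
    return aif.dt * toeplitz(ca, np.zeros_like(ca))


def _tsvd_factors(A: np.ndarray, regularization_fraction: float):
    if not (0.0 <= regularization_fraction < 1.0):
        raise ValueError("regularization_fraction must be in [0, 1)")
    U, s, Vt = np.linalg.svd(A)
    if s[0] <= 0:
        raise DegenerateAIFError("convolution operator is identically zero")
    keep = s >= max(regularization_fraction, _RANK_EPS) * s[0]
    if not keep.any():
        raise DegenerateAIFError("all singular values suppressed by the threshold")
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return U, s_inv, Vt


def tsvd_operator(A: np.ndarray, regularization_fraction: float) -> np.ndarray:
    """Truncated pseudo-inverse of A, reusable across many tissue curves."""
    U, s_inv, Vt = _tsvd_factors(A, regularization_fraction)
    return (Vt.T * s_inv) @ U.T


def deconvolve_tsvd(
    A: np.ndarray,
    c_tissue: ConcentrationSeries,
    regularization_fraction: float = 0.15,
) -> ResidueEstimate:
    """Recover fr = f*R(t) from A fr = c by truncated-SVD pseudo-inversion.

    With threshold 0 on a nonsingular noiseless system this reproduces the
    exact triangular solution.
    """
    c = c_tissue.values
    if A.shape[0] != A.shape[1] or A.shape[0] != c.size:
        raise ValueError("operator and tissue curve dimensions disagree")
    U, s_inv, Vt = _tsvd_factors(A, regularization_fraction)
    fr = Vt.T @ (s_inv * (U.T @ c))
    return ResidueEstimate(fr, c_tissue.dt, regularization_fraction)


def compute_parameters(
    fr: ResidueEstimate,
    c_tissue: ConcentrationSeries,
    aif: AIFCurve,
    mtt_mode: str = "central_volume",
) -> tuple[float, float, float]:
    """Perfusion parameters (PBF, PBV, MTT) from one voxel's estimates.

    Raises on a non-positive AIF area; returns NaNs (flagging an invalid
    voxel) when the recovered flow or tissue area is non-positive.
    """
    if abs(c_tissue.dt - aif.dt) > 1e-9:
        raise ValueError("tissue curve and AIF must share dt")
    if c_tissue.values.size != aif.values.size:
        raise ValueError("tissue curve and AIF must share length")
    if aif.area <= 0:
        raise ZeroDivisionError("non-positive AIF area")
    pbf = 6000.0 * float(fr.fr_values.max())
    pbv = 100.0 * c_tissue.area / aif.area
    if pbf <= 0 or pbv <= 0:
        return np.nan, np.nan, np.nan
    if mtt_mode == "central_volume":
        mtt = 60.0 * pbv / pbf
    elif mtt_mode == "residue_area":
        peak = float(fr.fr_values.max())
        mtt = float(fr.dt * fr.fr_values.sum() / peak)
    else:
        raise ValueError(f"unknown mtt mode {mtt_mode!r}")
    return pbf, pbv, mtt


def make_maps(
    series: DynamicSeries,
    aif: AIFCurve,
    mask: np.ndarray,
    config: KineticsConfig | None = None,
) -> PerfusionMaps:
    """Apply the deconvolution to every masked voxel and assemble maps.

    The SVD of the shared convolution operator is computed once; each
    voxel's residue is a single matrix-vector product. Voxels whose
    recovered flow or tissue area is non-positive are excluded (NaN in the
    maps, counted in ``n_excluded``).
    """
    cfg = config or KineticsConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask shape does not match the series grid")
    if not mask.any():
        raise ValueError("empty analysis mask")

    A = build_convolution_matrix(aif)
    pinv = tsvd_operator(A, cfg.regularization_fraction)

    curves = _convert(series.values[mask], series.n_baseline, cfg.conversion)
    fr_all = curves @ pinv.T  # (n_voxels, n_frames)

    dt = series.dt
    aif_area = aif.area
    if aif_area <= 0:
        raise ZeroDivisionError("non-positive AIF area")
    pbf_v = 6000.0 * fr_all.max(axis=1)
    pbv_v = 100.0 * dt * curves.sum(axis=1) / aif_area
    valid = np.isfinite(pbf_v) & np.isfinite(pbv_v) & (pbf_v > 0) & (pbv_v > 0)
    if cfg.mtt_mode == "central_volume":
        with np.errstate(divide="ignore", invalid="ignore"):
            mtt_v = 60.0 * pbv_v / pbf_v
    else:
        peak = fr_all.max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mtt_v = dt * fr_all.sum(axis=1) / peak

    shape = series.grid_shape
    pbf = np.full(shape, np.nan)
    pbv = np.full(shape, np.nan)
    mtt = np.full(shape, np.nan)
    valid_mask = np.zeros(shape, dtype=bool)
    idx = np.where(mask)
    for arr, vals in ((pbf, pbf_v), (pbv, pbv_v), (mtt, mtt_v)):
        arr[idx] = np.where(valid, vals, np.nan)
    valid_mask[idx] = valid
    return PerfusionMaps(
        pbf=pbf,
        pbv=pbv,
        mtt=mtt,
        valid_mask=valid_mask,
        voxel_size=series.voxel_size,
        n_excluded=int((~valid).sum()),
    )
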