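"""Synthetic DCE phantoms and cohorts with known ground truth.

This module emulates, end to end, the data a dynamic contrast-enhanced
thoracic MR protocol produces: a first-pass gamma-variate bolus in the
pulmonary trunk, tissue enhancement generated by the indicator-dilution
forward model C_t(t) = f * (C_a (*) R)(t), and a cohort of subjects whose
per-side perfusion summaries follow configurable group means, SDs and
inter-side correlations, with spirometry tied to ipsilateral flow by a
linear link.

Two deliberate simplifications (documented in docs/methods.md): the signal
model is a linear gain between concentration and relative enhancement, and
noise is additive Gaussian on the signal. Voxel curves are synthesized by
the same discrete convolution the quantification stage inverts, so every
rendered voxel is recomputable by a direct convolution oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .containers import DynamicSeries

__all__ = [
    "SubjectPhantom",
    "KineticGroundTruth",
    "AIFParams",
    "CohortSpec",
    "SpirometryLink",
    "SamplingError",
    "make_phantom",
    "gamma_variate_aif",
    "tissue_curve",
    "render_dce",
    "generate_cohort",
    "render_subject",
    "cdh_cohort_spec",
    "control_cohort_spec",
]

Side = Literal["left", "right"]

# Per-lung-minute flow f [1/s] relates to PBF [mL/100 mL/min] by 1/6000.
PBF_TO_PER_SECOND = 1.0 / 6000.0


class SamplingError(RuntimeError):
    """Raised when positive-truncated sampling fails after bounded retries."""


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject substream: the subject index is mixed into the seed so
    cohorts are stable under changes of the subject count."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class SubjectPhantom:
    """Voxel label masks of one synthetic thorax.

    The four masks are pairwise disjoint. Hilar macrovessel voxels are
    carved out of the anatomical lung ellipsoids, so ``lung | vessel``
    reconstitutes the full lung territory of each side.
    """

    grid_shape: tuple[int, int, int]
    left_lung_mask: np.ndarray
    right_lung_mask: np.ndarray
    trunk_mask: np.ndarray
    vessel_mask: np.ndarray
    affected_side: Side

    def __post_init__(self) -> None:
        masks = [self.left_lung_mask, self.right_lung_mask, self.trunk_mask, self.vessel_mask]
        for m in masks:
            if m.shape != tuple(self.grid_shape):
                raise ValueError("mask shape does not match grid_shape")
        if not (self.left_lung_mask.any() and self.right_lung_mask.any()):
            raise ValueError("lung masks must be non-empty")
        if not self.trunk_mask.any():
            raise ValueError("trunk mask must be non-empty")
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValueError("phantom masks must be pairwise disjoint")

    def lung_mask(self, side: Side) -> np.ndarray:
        return self.left_lung_mask if side == "left" else self.right_lung_mask


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(
    grid_shape: tuple[int, int, int],
    affected_side: Side,
    seed: int,
    volume_ratio: float = 0.9,
) -> SubjectPhantom:
    """Build a two-lung phantom with a pulmonary-trunk ROI and hilar vessels.

    The affected (hernia-side) lung is shrunk by ``volume_ratio`` so its
    voxel count is strictly smaller than the contralateral one, emulating
    the ipsilateral volume deficit. Geometry is jittered deterministically
    by ``seed``.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or any(n < 16 for n in grid_shape):
        raise ValueError(f"grid {grid_shape} too small: each dimension must be >= 16")
    if affected_side not in ("left", "right"):
        raise ValueError(f"unknown side {affected_side!r}")
    if not (0 < volume_ratio < 1):
        raise ValueError("volume_ratio must be in (0, 1)")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF0]))
    nx, ny, nz = grid_shape
    # One shared jitter keeps the two lungs comparable, so the volume_ratio
    # shrink of the affected side survives voxelization on small grids.
    jitter = rng.uniform(0.95, 1.05, size=3)

    base_axes = np.array([0.155 * nx, 0.30 * ny, 0.32 * nz]) * jitter
    shrink = volume_ratio ** (1.0 / 3.0)
    axes = {"left": base_axes.copy(), "right": base_axes.copy()}
    axes[affected_side] = axes[affected_side] * shrink

    centers = {
        "left": (0.28 * nx, 0.52 * ny, 0.50 * nz),
        "right": (0.72 * nx, 0.52 * ny, 0.50 * nz),
    }
    left = _ellipsoid(grid_shape, centers["left"], axes["left"])
    right = _ellipsoid(grid_shape, centers["right"], axes["right"])

    # Pulmonary trunk: short cylinder on the midline, anterior to the lungs.
    radius = max(1.4, 0.045 * nx)
    gx, gy = np.ogrid[0:nx, 0:ny]
    disc = ((gx - 0.5 * nx) ** 2 + (gy - 0.18 * ny) ** 2) <= radius**2
    trunk = np.zeros(grid_shape, dtype=bool)
    z0, z1 = int(0.40 * nz), max(int(0.40 * nz) + 2, int(0.60 * nz))
    trunk[:, :, z0:z1] = disc[:, :, None]
    trunk &= ~(left | right)
    if not trunk.any():
        raise ValueError("trunk construction failed for this grid")

    # Hilar macrovessels: small spheres at the medial edge of each lung,
    # carved out of the lung masks.
    vessel = np.zeros(grid_shape, dtype=bool)
    r_vessel = max(1.2, 0.04 * min(grid_shape))
    for side, sign in (("left", 1.0), ("right", -1.0)):
        cx, cy, cz = centers[side]
        hx = cx + sign * 0.75 * axes[side][0]
        vessel |= _ellipsoid(grid_shape, (hx, cy, cz), (r_vessel,) * 3)
    vessel &= left | right
    left &= ~vessel
    right &= ~vessel

    # The shrunken ellipsoid can tie on voxel counts for tiny grids; verify.
    affected = left if affected_side == "left" else right
    other = right if affected_side == "left" else left
    if affected.sum() >= other.sum():
        raise ValueError("grid too small to resolve the ipsilateral volume deficit")

    return SubjectPhantom(grid_shape, left, right, trunk, vessel, affected_side)


# ---------------------------------------------------------------------------
# Kinetic ground truth
# ---------------------------------------------------------------------------

@dataclass
class KineticGroundTruth:
    """Voxelwise ground-truth perfusion parameters of a phantom.

    The central-volume identity mtt = 60 * pbv / pbf holds exactly on
    every defined voxel by construction.
    """

    pbf_map: np.ndarray  # mL/100 mL/min
    pbv_map: np.ndarray  # mL/100 mL
    mtt_map: np.ndarray  # s
    residue_model: str = "exponential"

    @classmethod
    def from_side_values(
        cls,
        phantom: SubjectPhantom,
        pbf: dict[str, float],
        mtt: dict[str, float],
        vessel_mtt_factor: float = 10.0,
        residue_model: str = "exponential",
    ) -> "KineticGroundTruth":
        """Uniform per-side PBF and MTT; voxel PBV derived as pbf*mtt/60.

        Macrovessel voxels keep their side's flow but carry a
        ``vessel_mtt_factor`` longer transit time, i.e. a proportionally
        larger blood volume, which is what makes them separable by a
        PBV-percentile cut downstream.
        """
        shape = phantom.grid_shape
        pbf_map = np.full(shape, np.nan)
        mtt_map = np.full(shape, np.nan)
        mid_x = shape[0] / 2.0
        xs = np.arange(shape[0])[:, None, None]
        vessel_left = phantom.vessel_mask & np.broadcast_to(xs < mid_x, shape)
        for side in ("left", "right"):
            if pbf[side] <= 0 or mtt[side] <= 0:
                raise ValueError("ground-truth PBF and MTT must be positive")
            lung = phantom.lung_mask(side)
            vessel = vessel_left if side == "left" else (phantom.vessel_mask & ~vessel_left)
            pbf_map[lung] = pbf[side]
            mtt_map[lung] = mtt[side]
            pbf_map[vessel] = pbf[side]
            mtt_map[vessel] = mtt[side] * vessel_mtt_factor
        pbv_map = pbf_map * mtt_map / 60.0
        return cls(pbf_map, pbv_map, mtt_map, residue_model)


# ---------------------------------------------------------------------------
# Bolus and forward model
# ---------------------------------------------------------------------------

@dataclass
class AIFParams:
    """Gamma-variate bolus parameters for the arterial input function.

    ``t0`` defaults (at render time) to the end of the baseline frames;
    ``alpha`` and ``beta`` shape a realistic few-second first pass with the
    peak at t0 + alpha*beta.
    """

    t0: float | None = None
    alpha: float = 3.0
    beta: float = 1.5   # s
    amplitude: float = 1.0  # concentration a.u.


def gamma_variate_aif(
    t: np.ndarray,
    t0: float,
    alpha: float,
    beta: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Gamma-variate bolus A*((t-t0)/(alpha*beta))^alpha * exp(alpha-(t-t0)/beta).

    Zero for t <= t0 (causality); the single interior maximum sits at
    t0 + alpha*beta where the value equals ``amplitude``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > t0
    tau = (t[m] - t0) / (alpha * beta)
    out[m] = amplitude * tau**alpha * np.exp(alpha - (t[m] - t0) / beta)
    return out


def residue_samples(t: np.ndarray, mtt: float, model: str) -> np.ndarray:
    """Residue function R(t) sampled at the given times; R(0) = 1."""
    if model == "exponential":
        return np.exp(-t / mtt)
    if model == "boxcar":
        return (t < mtt).astype(float)
    raise ValueError(f"unknown residue model {model!r}")


def tissue_curve(
    aif: np.ndarray,
    pbf: float,
    mtt: float,
    residue_model: str = "exponential",
    dt: float = 1.5,
) -> np.ndarray:
    """Tissue concentration by the discrete causal convolution f*(C_a (*) R).

    ``f = pbf/6000`` converts mL/100 mL/min to 1/s. The output has the
    same length as the input AIF.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if pbf <= 0 or mtt <= 0:
        raise ValueError("pbf and mtt must be positive")
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    t = np.arange(n) * dt
    R = residue_samples(t, mtt, residue_model)
    f = pbf * PBF_TO_PER_SECOND
    return f * dt * np.convolve(aif, R)[:n]


def render_dce(
    phantom: SubjectPhantom,
    ground_truth: KineticGroundTruth,
    acquisition: AcquisitionConfig,
    aif_params: AIFParams | None = None,
) -> DynamicSeries:
    """Render the 4D dynamic series of one phantom.

    Lung and vessel voxels carry S0*(1 + k*C_t(t)) with C_t from the
    forward convolution of that voxel's ground truth; trunk voxels carry
    the arterial bolus; everything else stays at baseline. Gaussian noise
    of SD ``noise_sigma`` is added, seeded by ``acquisition.seed``.
    """
    if ground_truth.pbf_map.shape != tuple(phantom.grid_shape):
        raise ValueError("ground-truth maps do not match the phantom grid")
    ap = aif_params or AIFParams()
    t0 = ap.t0 if ap.t0 is not None else acquisition.n_baseline * acquisition.frame_interval
    t = acquisition.frame_times
    ca = gamma_variate_aif(t, t0, ap.alpha, ap.beta, ap.amplitude)

    s0 = acquisition.baseline_signal
    k = acquisition.enhancement_gain
    values = np.full(phantom.grid_shape + (acquisition.n_frames,), s0, dtype=float)
    values[phantom.trunk_mask] = s0 * (1.0 + k * ca)

    tissue = phantom.left_lung_mask | phantom.right_lung_mask | phantom.vessel_mask
    pbf_v = ground_truth.pbf_map[tissue]
    mtt_v = ground_truth.mtt_map[tissue]
    curves = np.empty((pbf_v.size, acquisition.n_frames))
    # Voxels sharing (pbf, mtt) share a curve; compute each unique pair once.
    pairs = np.stack([pbf_v, mtt_v], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    for idx, (pbf, mtt) in enumerate(uniq):
        ct = tissue_curve(ca, pbf, mtt, ground_truth.residue_model, acquisition.frame_interval)
        curves[inverse == idx] = s0 * (1.0 + k * ct)
    values[tissue] = curves

    if acquisition.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(acquisition.seed), 0xD1]))
        values = values + rng.normal(0.0, acquisition.noise_sigma, size=values.shape)

    return DynamicSeries(values, t, acquisition.voxel_size, acquisition.n_baseline)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SpirometryLink:
    """Linear links from ipsilateral PBF to spirometric % predicted values.

    Each percentage is intercept + slope*PBF_ipsi + N(0, resid_sd); the
    Tiffeneau index is drawn independently around its own mean.
    """

    fev1_slope: float
    fev1_intercept: float
    fev1_resid_sd: float
    fvc_slope: float
    fvc_intercept: float
    fvc_resid_sd: float
    tiffeneau_mean: float = 0.78
    tiffeneau_sd: float = 0.11


@dataclass
class CohortSpec:
    """Distributional specification of one subject group.

    Each perfusion parameter and the lung volume are sampled, per subject,
    from a bivariate normal over (ipsilateral, contralateral) with the
    stated means/SDs and inter-side correlation ``rho``, truncated to
    positive values by resampling. When ECMO mixture components are given,
    the ipsilateral PBF mean/SD are taken from the subject's ECMO stratum.
    """

    n_subjects: int
    group: str  # "CDH" or "control"
    pbf: dict = field(default_factory=dict)       # {"ipsi": (mean, sd), "contra": (...)}
    pbv: dict = field(default_factory=dict)
    mtt: dict = field(default_factory=dict)
    volume: dict = field(default_factory=dict)
    rho: float = 0.5
    ecmo_fraction: float = 0.0
    ecmo_pbf_ipsi: tuple[float, float] | None = None
    non_ecmo_pbf_ipsi: tuple[float, float] | None = None
    right_side_fraction: float = 0.0
    spirometry: SpirometryLink | None = None
    spirometry_fraction: float = 1.0
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if not (0.0 <= self.ecmo_fraction <= 1.0):
            raise ValueError("ecmo_fraction must lie in [0, 1]")
        for block in (self.pbf, self.pbv, self.mtt, self.volume):
            for mean, sd in block.values():
                if sd < 0:
                    raise ValueError("SDs must be non-negative")


def cdh_cohort_spec(n_subjects: int = 54, seed: int = 0, rho: float = 0.5) -> CohortSpec:
    """Default CDH-group spec: published per-side means/SDs, 40.7% ECMO
    (with the ECMO/non-ECMO ipsilateral-PBF mixture whose pooled moments
    reproduce the overall 60.4 +/- 23.8), 18.5% right-sided hernias, and
    spirometry available in a 43/54 subset linked to ipsilateral PBF."""
    # FEV1: r = 0.45 against ipsi PBF, marginal 75.98 +/- 22.82 %.
    fev1_slope = 0.45 * 22.82 / 23.8
    fvc_slope = 0.39 * 20.69 / 23.8
    link = SpirometryLink(
        fev1_slope=fev1_slope,
        fev1_intercept=75.98 - fev1_slope * 60.4,
        fev1_resid_sd=22.82 * float(np.sqrt(1 - 0.45**2)),
        fvc_slope=fvc_slope,
        fvc_intercept=74.79 - fvc_slope * 60.4,
        fvc_resid_sd=20.69 * float(np.sqrt(1 - 0.39**2)),
    )
    return CohortSpec(
        n_subjects=n_subjects,
        group="CDH",
        pbf={"ipsi": (60.4, 23.8), "contra": (90.0, 26.5)},
        pbv={"ipsi": (5.69, 2.19), "contra": (8.08, 2.18)},
        mtt={"ipsi": (6.33, 1.65), "contra": (5.95, 1.28)},
        volume={"ipsi": (432.4, 128.6), "contra": (481.0, 105.3)},
        rho=rho,
        ecmo_fraction=0.407,
        ecmo_pbf_ipsi=(49.7, 14.3),
        non_ecmo_pbf_ipsi=(67.8, 26.1),
        right_side_fraction=0.185,
        spirometry=link,
        spirometry_fraction=43.0 / 54.0,
        seed=seed,
    )


def control_cohort_spec(n_subjects: int = 10, seed: int = 0, rho: float = 0.84) -> CohortSpec:
    """Default control-group spec: published control means/SDs; no ECMO,
    no spirometry. The inter-side correlation 0.84 is derived from the
    printed control PBF-ratio SD by the delta method."""
    return CohortSpec(
        n_subjects=n_subjects,
        group="control",
        pbf={"ipsi": (93.3, 16.09), "contra": (95.4, 13.5)},
        pbv={"ipsi": (7.92, 2.65), "contra": (8.62, 2.00)},
        mtt={"ipsi": (5.82, 0.95), "contra": (5.86, 0.77)},
        volume={"ipsi": (462.3, 159.1), "contra": (480.4, 160.2)},
        rho=rho,
        ecmo_fraction=0.0,
        spirometry=None,
        spirometry_fraction=0.0,
        seed=seed,
    )


def _truncated_bivariate(
    rng: np.random.Generator,
    mean_i: float,
    sd_i: float,
    mean_c: float,
    sd_c: float,
    rho: float,
    max_retries: int,
) -> tuple[float, float]:
    cov = rho * sd_i * sd_c
    mean = np.array([mean_i, mean_c])
    sigma = np.array([[sd_i**2, cov], [cov, sd_c**2]])
    for _ in range(max_retries):
        x = rng.multivariate_normal(mean, sigma, method="cholesky")
        if x[0] > 0 and x[1] > 0:
            return float(x[0]), float(x[1])
    raise SamplingError(
        f"positive truncation failed after {max_retries} draws "
        f"(means {mean_i}, {mean_c}; are they many SDs below zero?)"
    )


@dataclass
class Cohort:
    """Generated cohort: ground-truth subject table plus spirometry table."""

    subjects: pd.DataFrame
    spirometry: pd.DataFrame
    rendered: dict | None = None


def generate_cohort(
    spec: CohortSpec,
    render: bool = False,
    acquisition: AcquisitionConfig | None = None,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
) -> Cohort:
    """Sample one subject group from its distributional spec.

    Returns a subject table with per-side PBF/PBV/MTT/volume columns, the
    per-subject ipsi/contra PBF ratio, ECMO status and hernia side, plus a
    spirometry table for the subset with lung-function data. With
    ``render=True`` each subject additionally gets a phantom, ground truth
    and rendered :class:`DynamicSeries` keyed by subject id.
    """
    prefix = "CDH" if spec.group == "CDH" else "CTL"
    rows = []
    spiro_rows = []
    rendered: dict = {}
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, i)
        ecmo = bool(rng.random() < spec.ecmo_fraction)
        if spec.group == "CDH":
            side = "right" if rng.random() < spec.right_side_fraction else "left"
        else:
            side = "left"  # convention: "ipsilateral" in controls means left

        pbf_ipsi_stats = spec.pbf["ipsi"]
        if ecmo and spec.ecmo_pbf_ipsi is not None:
            pbf_ipsi_stats = spec.ecmo_pbf_ipsi
        elif not ecmo and spec.non_ecmo_pbf_ipsi is not None:
            pbf_ipsi_stats = spec.non_ecmo_pbf_ipsi

        pbf_i, pbf_c = _truncated_bivariate(
            rng, *pbf_ipsi_stats, *spec.pbf["contra"], spec.rho, spec.max_retries
        )
        pbv_i, pbv_c = _truncated_bivariate(
            rng, *spec.pbv["ipsi"], *spec.pbv["contra"], spec.rho, spec.max_retries
        )
        mtt_i, mtt_c = _truncated_bivariate(
            rng, *spec.mtt["ipsi"], *spec.mtt["contra"], spec.rho, spec.max_retries
        )
        vol_i, vol_c = _truncated_bivariate(
            rng, *spec.volume["ipsi"], *spec.volume["contra"], spec.rho, spec.max_retries
        )

        subject_id = f"{prefix}-{i + 1:03d}"
        spiro_available = bool(
            spec.spirometry is not None and rng.random() < spec.spirometry_fraction
        )
        rows.append(
            {
                "subject_id": subject_id,
                "group": spec.group,
                "hernia_side": side if spec.group == "CDH" else "",
                "ecmo": ecmo,
                "pbf_ipsi": pbf_i,
                "pbf_contra": pbf_c,
                "pbv_ipsi": pbv_i,
                "pbv_contra": pbv_c,
                "mtt_ipsi": mtt_i,
                "mtt_contra": mtt_c,
                "volume_ipsi": vol_i,
                "volume_contra": vol_c,
                "pbf_ratio": pbf_i / pbf_c,
                "spirometry_available": spiro_available,
            }
        )

        if spiro_available:
            link = spec.spirometry
            fev1 = link.fev1_intercept + link.fev1_slope * pbf_i + rng.normal(0, link.fev1_resid_sd)
            fvc = link.fvc_intercept + link.fvc_slope * pbf_i + rng.normal(0, link.fvc_resid_sd)
            tiff = rng.normal(link.tiffeneau_mean, link.tiffeneau_sd)
            spiro_rows.append(
                {
                    "subject_id": subject_id,
                    "fev1_pct": max(fev1, 1.0),
                    "fvc_pct": max(fvc, 1.0),
                    "tiffeneau": float(np.clip(tiff, 0.2, 1.2)),
                }
            )

        if render:
            acq = acquisition or AcquisitionConfig()
            rendered[subject_id] = render_subject(
                rows[-1], acq, grid_shape, seed=spec.seed, subject_index=i
            )

    subjects = pd.DataFrame(rows)
    spiro_cols = ["subject_id", "fev1_pct", "fvc_pct", "tiffeneau"]
    spirometry = pd.DataFrame(spiro_rows, columns=spiro_cols)
    return Cohort(subjects, spirometry, rendered if render else None)


def render_subject(
    row: dict,
    acquisition: AcquisitionConfig,
    grid_shape: tuple[int, int, int],
    seed: int,
    subject_index: int,
) -> tuple[SubjectPhantom, KineticGroundTruth, DynamicSeries]:
    """Render one cohort subject's 4D series from its sampled side values.

    The phantom's voxel ground truth uses the subject's sampled PBF and MTT
    per side (voxel PBV follows from the central-volume identity).
    """
    ipsi = row["hernia_side"] if row.get("hernia_side") else "left"
    contra = "right" if ipsi == "left" else "left"
    sub_seed = int(
        np.random.SeedSequence([int(seed), int(subject_index), 0xA7]).generate_state(1)[0]
        % (2**31)
    )
    phantom = make_phantom(grid_shape, affected_side=ipsi, seed=sub_seed)
    truth = KineticGroundTruth.from_side_values(
        phantom,
        pbf={ipsi: row["pbf_ipsi"], contra: row["pbf_contra"]},
        mtt={ipsi: row["mtt_ipsi"], contra: row["mtt_contra"]},
    )
    acq = replace(acquisition, seed=sub_seed)
    series = render_dce(phantom, truth, acq)
    return phantom, truth, series
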