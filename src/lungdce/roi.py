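"""Per-lung-side ROI analysis: vessel exclusion, side summaries, role
assignment and the ipsi/contra PBF ratio."""

from __future__ import annotations

import numpy as np

from .config import ROIConfig
from .containers import PerfusionMaps, SideSummary, SubjectRecord

__all__ = [
    "VesselExclusionError",
    "exclude_macrovessels",
    "side_summary",
    "assign_roles",
    "pbf_ratio",
    "summarize_subject",
]


class VesselExclusionError(ValueError):
    """Vessel exclusion removed an implausible share of the lung."""


def exclude_macrovessels(
    maps: PerfusionMaps,
    lung_mask: np.ndarray,
    vessel_mask: np.ndarray | None = None,
    percentile_cutoff: float | None = None,
    config: ROIConfig | None = None,
) -> np.ndarray:
    """Refine a lung mask by removing hilar macrovessels.

    With an explicit ``vessel_mask`` the voxels are subtracted directly.
    Otherwise voxels whose PBV exceeds the stated percentile (default the
    99th) of the in-mask PBV distribution are removed — macrovessels carry
    a much larger blood-volume fraction than parenchyma. Removal of more
    than ``max_excluded_fraction`` of the mask (default 20%) signals an
    implausible cutoff and raises.
    """
    cfg = config or ROIConfig()
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise ValueError("empty lung mask")
    n_before = int(lung_mask.sum())

    if vessel_mask is not None:
        refined = lung_mask & ~np.asarray(vessel_mask, dtype=bool)
    else:
        pct = cfg.vessel_percentile if percentile_cutoff is None else percentile_cutoff
        pbv = maps.pbv[lung_mask]
        finite = pbv[np.isfinite(pbv)]
        if finite.size == 0:
            raise ValueError("no valid PBV voxels inside the lung mask")
        cutoff = np.percentile(finite, pct)
        refined = lung_mask & ~(np.nan_to_num(maps.pbv, nan=-np.inf) > cutoff)

    n_removed = n_before - int(refined.sum())
    if not refined.any() or n_removed > cfg.max_excluded_fraction * n_before:
        raise VesselExclusionError(
            f"vessel exclusion removed {n_removed}/{n_before} voxels "
            f"(limit {cfg.max_excluded_fraction:.0%})"
        )
    return refined


def side_summary(
    maps: PerfusionMaps,
    mask: np.ndarray,
    voxel_size: float | None = None,
    subject_id: str = "",
    side_role: str = "",
) -> SideSummary:
    """Unweighted means of PBF/PBV/MTT over the valid voxels of one side.

    Lung volume is the voxel count times the voxel volume; at 2 mm
    isotropic resolution one voxel is 0.008 mL.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty side mask")
    vs = maps.voxel_size if voxel_size is None else voxel_size
    valid = mask & maps.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid voxels inside the side mask")
    voxel_volume_ml = (vs / 10.0) ** 3  # mm -> cm; 1 cm^3 = 1 mL
    return SideSummary(
        subject_id=subject_id,
        side_role=side_role,
        mean_pbf=float(maps.pbf[valid].mean()),
        mean_pbv=float(maps.pbv[valid].mean()),
        mean_mtt=float(maps.mtt[valid].mean()),
        lung_volume=float(mask.sum() * voxel_volume_ml),
        n_voxels=int(mask.sum()),
    )


def assign_roles(group: str, hernia_side: str | None = None) -> tuple[str, str]:
    """(ipsilateral, contralateral) side labels for one subject.

    CDH subjects: ipsilateral is the hernia side. Controls have no hernia;
    by convention their left lung is labelled ipsilateral so group
    comparisons stay side-matched to the predominantly left-sided CDH
    cohort.
    """
    if group == "CDH":
        if hernia_side not in ("left", "right"):
            raise ValueError("CDH subject with unknown hernia side")
        ipsi = hernia_side
    elif group == "control":
        ipsi = "left"
    else:
        raise ValueError(f"unknown group {group!r}")
    contra = "right" if ipsi == "left" else "left"
    return ipsi, contra


def pbf_ratio(record: SubjectRecord) -> float:
    """Per-subject ipsilateral/contralateral mean-PBF ratio.

    Cohort statistics of the ratio are taken over per-subject ratios,
    never as a ratio of group means.
    """
    if record.contralateral.mean_pbf <= 0:
        raise ValueError("contralateral mean PBF must be positive")
    return record.ipsilateral.mean_pbf / record.contralateral.mean_pbf


def summarize_subject(
    maps: PerfusionMaps,
    left_mask: np.ndarray,
    right_mask: np.ndarray,
    subject_id: str,
    group: str,
    hernia_side: str | None = None,
    ecmo: bool = False,
    vessel_mask: np.ndarray | None = None,
    roi_config: ROIConfig | None = None,
) -> SubjectRecord:
    """Full per-subject ROI stage: vessel exclusion on each side's full
    lung territory, side summaries, role assignment and the PBF ratio."""
    ipsi_side, contra_side = assign_roles(group, hernia_side)
    masks = {"left": np.asarray(left_mask, bool), "right": np.asarray(right_mask, bool)}
    vessel_by_side = None
    if vessel_mask is not None:
        # Attribute vessel voxels to a side by midline position, then fold
        # them into that side's territory so the exclusion step sees the
        # full lung including its hilar vessels.
        vessel_mask = np.asarray(vessel_mask, bool)
        mid = maps.pbf.shape[0] // 2
        split = np.zeros_like(vessel_mask)
        split[:mid] = True
        vessel_by_side = {"left": vessel_mask & split, "right": vessel_mask & ~split}
        masks = {s: masks[s] | vessel_by_side[s] for s in masks}

    summaries = {}
    for side, mask in masks.items():
        vessels = vessel_by_side[side] if vessel_by_side is not None else None
        refined = exclude_macrovessels(maps, mask, vessel_mask=vessels, config=roi_config)
        role = "ipsilateral" if side == ipsi_side else "contralateral"
        summaries[role] = side_summary(
            maps, refined, subject_id=subject_id, side_role=role
        )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        hernia_side=hernia_side,
        ecmo=ecmo,
        ipsilateral=summaries["ipsilateral"],
        contralateral=summaries["contralateral"],
    )
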