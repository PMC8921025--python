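"""Subject-level perfusion model: dynamic series in, fitted maps and
per-side summaries out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KineticsConfig, ROIConfig
from .containers import AIFCurve, DynamicSeries, PerfusionMaps, SubjectRecord
from .kinetics import extract_aif, make_maps
from .roi import summarize_subject

__all__ = ["PerfusionModel", "PerfusionResults"]


@dataclass
class PerfusionResults:
    """Fitted perfusion quantification of one subject.

    Carries the voxel maps, the AIF actually used, the per-side summary
    record and quantification diagnostics (excluded-voxel count and the
    truncation level applied).
    """

    maps: PerfusionMaps
    aif: AIFCurve
    record: SubjectRecord
    regularization_fraction: float
    n_excluded: int

    def summary(self) -> str:
        r = self.record
        rows = [
            ("PBF (mL/100 mL/min)", r.ipsilateral.mean_pbf, r.contralateral.mean_pbf),
            ("PBV (mL/100 mL)", r.ipsilateral.mean_pbv, r.contralateral.mean_pbv),
            ("MTT (s)", r.ipsilateral.mean_mtt, r.contralateral.mean_mtt),
            ("Lung volume (mL)", r.ipsilateral.lung_volume, r.contralateral.lung_volume),
        ]
        lines = [
            f"Perfusion results — subject {r.subject_id} ({r.group})",
            "=" * 58,
            f"{'parameter':<26}{'ipsilateral':>14}{'contralateral':>16}",
        ]
        for name, ipsi, contra in rows:
            lines.append(f"{name:<26}{ipsi:>14.2f}{contra:>16.2f}")
        lines.append(f"PBF ratio (ipsi/contra)   {r.pbf_ratio:>14.3f}")
        lines.append(
            f"AIF ROI: {self.aif.source_roi_size} voxels; "
            f"TSVD truncation: {self.regularization_fraction:.0%}; "
            f"excluded voxels: {self.n_excluded}"
        )
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat row for the cohort subject table."""
        r = self.record
        return {
            "subject_id": r.subject_id,
            "group": r.group,
            "hernia_side": r.hernia_side or "",
            "ecmo": r.ecmo,
            "pbf_ipsi": r.ipsilateral.mean_pbf,
            "pbf_contra": r.contralateral.mean_pbf,
            "pbv_ipsi": r.ipsilateral.mean_pbv,
            "pbv_contra": r.contralateral.mean_pbv,
            "mtt_ipsi": r.ipsilateral.mean_mtt,
            "mtt_contra": r.contralateral.mean_mtt,
            "volume_ipsi": r.ipsilateral.lung_volume,
            "volume_contra": r.contralateral.lung_volume,
            "pbf_ratio": r.pbf_ratio,
        }

    def plot_maps(self, slice_index: int | None = None):
        """Axial PBF/PBV/MTT panels through the given slice (matplotlib)."""
        import matplotlib.pyplot as plt

        z = slice_index if slice_index is not None else self.maps.pbf.shape[2] // 2
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (arr, title, unit) in zip(
            axes,
            (
                (self.maps.pbf, "PBF", "mL/100 mL/min"),
                (self.maps.pbv, "PBV", "mL/100 mL"),
                (self.maps.mtt, "MTT", "s"),
            ),
        ):
            im = ax.imshow(arr[:, :, z].T, origin="lower", cmap="inferno")
            ax.set_title(f"{title} ({unit})")
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        return fig


class PerfusionModel:
    """Indicator-dilution perfusion model for one dynamic series.

    Parameters
    ----------
    series : DynamicSeries
        The 4D signal.
    trunk_mask : ndarray of bool
        Arterial ROI in the pulmonary trunk (the AIF source).
    left_mask, right_mask : ndarray of bool
        Lung masks per side.
    vessel_mask : ndarray of bool, optional
        Explicit hilar macrovessel mask; without it, vessels are excluded
        by the PBV-percentile rule.
    """

    def __init__(
        self,
        series: DynamicSeries,
        trunk_mask: np.ndarray,
        left_mask: np.ndarray,
        right_mask: np.ndarray,
        vessel_mask: np.ndarray | None = None,
        subject_id: str = "subject",
        group: str = "CDH",
        hernia_side: str | None = "left",
        ecmo: bool = False,
        kinetics_config: KineticsConfig | None = None,
        roi_config: ROIConfig | None = None,
    ) -> None:
        self.series = series
        self.trunk_mask = np.asarray(trunk_mask, bool)
        self.left_mask = np.asarray(left_mask, bool)
        self.right_mask = np.asarray(right_mask, bool)
        self.vessel_mask = None if vessel_mask is None else np.asarray(vessel_mask, bool)
        self.subject_id = subject_id
        self.group = group
        self.hernia_side = hernia_side
        self.ecmo = ecmo
        self.kinetics_config = kinetics_config or KineticsConfig()
        self.roi_config = roi_config or ROIConfig()

    def fit(self) -> PerfusionResults:
        aif = extract_aif(self.series, self.trunk_mask, mode=self.kinetics_config.conversion)
        analysis_mask = self.left_mask | self.right_mask
        if self.vessel_mask is not None:
            analysis_mask = analysis_mask | self.vessel_mask
        maps = make_maps(self.series, aif, analysis_mask, self.kinetics_config)
        record = summarize_subject(
            maps,
            self.left_mask,
            self.right_mask,
            subject_id=self.subject_id,
            group=self.group,
            hernia_side=self.hernia_side,
            ecmo=self.ecmo,
            vessel_mask=self.vessel_mask,
            roi_config=self.roi_config,
        )
        return PerfusionResults(
            maps=maps,
            aif=aif,
            record=record,
            regularization_fraction=self.kinetics_config.regularization_fraction,
            n_excluded=maps.n_excluded,
        )
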