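"""NIfTI I/O for dynamic series, masks and parameter maps.

All image I/O goes through NIfTI-1 (.nii / .nii.gz): the header carries the
voxel geometry, the fourth pixdim carries the frame interval, and map units
are recorded in the header description field.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import DynamicSeries

__all__ = [
    "read_dynamic_series",
    "write_dynamic_series",
    "read_mask",
    "write_mask",
    "write_map",
    "read_map",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def write_dynamic_series(series: DynamicSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.values, _affine(series.voxel_size))
    img.header.set_zooms((series.voxel_size,) * 3 + (series.dt,))
    img.header["descrip"] = f"n_baseline={series.n_baseline}".encode()
    nib.save(img, str(path))


def read_dynamic_series(
    path: str | Path,
    frame_interval: float | None = None,
    n_baseline: int = 5,
) -> DynamicSeries:
    """Load a 4D dynamic series; geometry from the header.

    The frame interval is taken from the header's fourth pixdim, or from
    ``frame_interval`` when the header carries none.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D data")
    zooms = img.header.get_zooms()
    voxel_size = float(zooms[0])
    dt = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else None
    if dt is None:
        dt = frame_interval
    if dt is None or dt <= 0:
        raise ValueError(
            f"{path}: no positive frame interval in the header and none configured"
        )
    descrip = img.header["descrip"].tobytes().decode(errors="ignore")
    if "n_baseline=" in descrip:
        n_baseline = int(descrip.split("n_baseline=")[1].split("\x00")[0].split(";")[0])
    frame_times = np.arange(data.shape[3]) * dt
    return DynamicSeries(data, frame_times, voxel_size, n_baseline)


def write_mask(mask: np.ndarray, voxel_size: float, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D data")
    return data > 0


def write_map(values: np.ndarray, voxel_size: float, path: str | Path, units: str = "") -> None:
    img = nib.Nifti1Image(values.astype(np.float64), _affine(voxel_size))
    if units:
        img.header["descrip"] = units.encode()[:79]
    nib.save(img, str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {data.ndim}D data")
    return data, float(img.header.get_zooms()[0])
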