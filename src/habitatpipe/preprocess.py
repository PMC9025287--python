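"""Spatial and intensity conformance of three-phase DCE-MRI studies.

Every study is resampled to a common 1 mm isotropic grid (cubic B-spline
for intensities, nearest neighbour for the tumour ROI mask), and the
validation cohort's intensities are harmonised to the development cohort
by monotone quantile (histogram) matching, phase by phase.  The
reference histogram is built from tumour-ROI voxels pooled over the
development cohort: the tumour intensities are what feed the downstream
clustering, and pooling ROI voxels only keeps background air from
dominating the mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import SimpleITK as sitk

PHASES = ("pre", "early", "delayed")

__all__ = [
    "PHASES",
    "DCEStudy",
    "ReferenceHistogram",
    "resample_isotropic",
    "build_reference_histogram",
    "histogram_match",
    "load_study",
    "save_study",
]


@dataclass
class DCEStudy:
    """One patient's three-phase DCE-MRI acquisition.

    Volumes are numpy arrays indexed (i, j, k) with physical voxel size
    ``spacing`` (mm) along the same axes.  ``roi`` is a binary tumour
    mask on the same grid.
    """

    pid: str
    pre: np.ndarray
    early: np.ndarray
    delayed: np.ndarray
    roi: np.ndarray
    spacing: tuple[float, float, float]
    cohort: str = "development"

    def __post_init__(self) -> None:
        shapes = {self.pre.shape, self.early.shape, self.delayed.shape, self.roi.shape}
        if len(shapes) != 1:
            raise ValueError(f"phase/mask shapes differ: {shapes}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        for name in PHASES:
            vol = getattr(self, name)
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"non-finite intensities in phase {name!r}")
        self.roi = self.roi.astype(bool)
        if not self.roi.any():
            raise ValueError("ROI mask is empty")

    @property
    def phases(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in PHASES}

    def roi_intensities(self, phase: str) -> np.ndarray:
        return getattr(self, phase)[self.roi]


def _to_sitk(volume: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    # SimpleITK arrays are indexed (z, y, x); our arrays are (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.T).astype(np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def _resample_volume(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    new_spacing: tuple[float, float, float],
    interpolator: int,
) -> np.ndarray:
    img = _to_sitk(volume, spacing)
    # last output sample must stay inside the input grid so the spline
    # never extrapolates into the zero-fill region
    size = [
        max(1, int(np.floor((n - 1) * s / ns)) + 1)
        for n, s, ns in zip(img.GetSize(), img.GetSpacing(), new_spacing)
    ]
    res = sitk.Resample(
        img,
        size,
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        tuple(float(s) for s in new_spacing),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    return _from_sitk(res)


def resample_isotropic(
    study: DCEStudy, new_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> DCEStudy:
    """Resample a study to an isotropic grid (default 1x1x1 mm).

    Intensities are interpolated with a cubic B-spline and clipped at
    zero (the spline can overshoot near sharp edges and negative MR
    magnitudes are non-physical); the ROI mask uses nearest-neighbour
    interpolation and stays binary.  The physical extent of the volume
    is preserved to within one voxel.
    """
    if any(n <= 1 for n in study.pre.shape):
        raise ValueError(f"degenerate volume of shape {study.pre.shape}")
    new_spacing = tuple(float(s) for s in new_spacing)
    out = {}
    for name, vol in study.phases.items():
        res = _resample_volume(vol, study.spacing, new_spacing, sitk.sitkBSpline)
        out[name] = np.clip(res, 0.0, None)
    mask = _resample_volume(
        study.roi.astype(np.float64), study.spacing, new_spacing, sitk.sitkNearestNeighbor
    )
    return replace(
        study,
        pre=out["pre"],
        early=out["early"],
        delayed=out["delayed"],
        roi=mask > 0.5,
        spacing=new_spacing,
    )


@dataclass
class ReferenceHistogram:
    """Per-phase quantile table pooled over development-cohort ROI voxels."""

    quantiles: np.ndarray  # shape (n_quantiles,), in [0, 1]
    values: dict[str, np.ndarray]  # phase -> intensities at the quantiles

    def __post_init__(self) -> None:
        for phase, vals in self.values.items():
            if np.any(np.diff(vals) < 0):
                raise ValueError(f"quantile values not monotone for phase {phase!r}")

    @property
    def n_quantiles(self) -> int:
        return len(self.quantiles)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "quantiles": self.quantiles.tolist(),
            "values": {k: v.tolist() for k, v in self.values.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceHistogram":
        payload = json.loads(Path(path).read_text())
        return cls(
            quantiles=np.asarray(payload["quantiles"], dtype=float),
            values={k: np.asarray(v, dtype=float) for k, v in payload["values"].items()},
        )


def build_reference_histogram(
    studies: Iterable[DCEStudy], n_quantiles: int = 256
) -> ReferenceHistogram:
    """Pool ROI voxels of the development studies into a quantile table.

    The table has ``n_quantiles`` evenly spaced quantiles per phase (the
    same granularity as the 256-level feature quantisation used
    downstream).  Pooling is a bag-of-voxels operation, so the result
    does not depend on patient order.
    """
    pools: dict[str, list[np.ndarray]] = {name: [] for name in PHASES}
    for study in studies:
        for name in PHASES:
            pools[name].append(study.roi_intensities(name))
    if not pools["pre"]:
        raise ValueError("no studies supplied; cannot build reference histogram")
    q = np.linspace(0.0, 1.0, n_quantiles)
    values = {}
    for name, chunks in pools.items():
        pool = np.concatenate(chunks)
        if pool.size == 0:
            raise ValueError("pooled ROI is empty")
        values[name] = np.quantile(pool, q)
    return ReferenceHistogram(quantiles=q, values=values)


def _match_one(
    volume: np.ndarray, roi: np.ndarray, ref_q: np.ndarray, ref_v: np.ndarray
) -> np.ndarray:
    src = np.quantile(volume[roi], ref_q)
    # Monotone source-quantile -> reference-quantile map; out-of-range
    # values clamp to the reference extremes via np.interp semantics.
    flat = np.interp(volume.ravel(), src, ref_v)
    return flat.reshape(volume.shape)


def histogram_match(study: DCEStudy, reference: ReferenceHistogram) -> DCEStudy:
    """Harmonise a study's intensities to the reference cohort, per phase.

    The mapping is estimated from the study's ROI voxels (matching what
    feeds clustering) and applied to the whole volume.
    """
    out = {}
    for name, vol in study.phases.items():
        if name not in reference.values:
            raise KeyError(f"phase {name!r} missing from reference histogram")
        out[name] = _match_one(vol, study.roi, reference.quantiles, reference.values[name])
    return replace(study, pre=out["pre"], early=out["early"], delayed=out["delayed"])


def save_study(study: DCEStudy, directory: str | Path) -> dict[str, str]:
    """Write the four volumes of a study as NIfTI files; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(study.spacing) + [1.0])
    paths = {}
    for name, vol in study.phases.items():
        p = directory / f"{study.pid}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), p)
        paths[name] = str(p)
    p = directory / f"{study.pid}_mask.nii.gz"
    nib.save(nib.Nifti1Image(study.roi.astype(np.uint8), affine), p)
    paths["mask"] = str(p)
    return paths


def load_study(
    directory: str | Path, pid: str, cohort: str = "development"
) -> DCEStudy:
    """Read a study previously written by :func:`save_study`."""
    directory = Path(directory)
    vols: dict[str, np.ndarray] = {}
    spacing = None
    for name in PHASES + ("mask",):
        img = nib.load(directory / f"{pid}_{name}.nii.gz")
        vols[name] = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DCEStudy(
        pid=pid,
        pre=vols["pre"].astype(np.float64),
        early=vols["early"].astype(np.float64),
        delayed=vols["delayed"].astype(np.float64),
        roi=vols["mask"] > 0.5,
        spacing=spacing,
        cohort=cohort,
    )
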