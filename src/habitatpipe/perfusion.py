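"""Voxelwise perfusion parametric maps from three-phase DCE-MRI.

Three maps summarise each voxel's enhancement kinetics:

* wash-in      ``Ein  = I_early - I_pre``
* washout      ``Eout = I_early - I_delayed``  (negative = persistent)
* washout rate ``RWO  = (I_early - I_delayed) / I_early`` when the
  delayed signal has dropped below the early signal, and 0 otherwise
  (a non-decreasing curve is treated as "no washout").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from habitatpipe.preprocess import DCEStudy

__all__ = ["PerfusionMaps", "compute_perfusion_maps", "save_maps"]


@dataclass
class PerfusionMaps:
    """Wash-in, washout and washout-ratio volumes on the study grid."""

    pid: str
    ein: np.ndarray
    eout: np.ndarray
    rwo: np.ndarray
    roi: np.ndarray
    spacing: tuple[float, float, float]

    def pfv(self) -> np.ndarray:
        """ROI voxels as an (n, 3) array of (Ein, Eout, RWO) rows."""
        return np.column_stack(
            [self.ein[self.roi], self.eout[self.roi], self.rwo[self.roi]]
        )


def compute_perfusion_maps(study: DCEStudy, roi_only: bool = True) -> PerfusionMaps:
    """Compute the three perfusion maps voxel by voxel.

    With ``roi_only`` (the default) voxels outside the tumour mask are
    zeroed — every downstream use is ROI-restricted.  Pass
    ``roi_only=False`` for whole-volume maps (visualisation overlays).

    The washout ratio is defined as 0 where the early-phase signal is 0:
    with non-negative clipped intensities a zero early signal cannot sit
    above the delayed signal, so the branch only makes the map total.
    """
    pre, early, delayed = study.pre, study.early, study.delayed
    ein = early - pre
    eout = early - delayed
    with np.errstate(divide="ignore", invalid="ignore"):
        rwo = np.where((delayed < early) & (early != 0), eout / early, 0.0)
    if roi_only:
        keep = study.roi
        ein = np.where(keep, ein, 0.0)
        eout = np.where(keep, eout, 0.0)
        rwo = np.where(keep, rwo, 0.0)
    return PerfusionMaps(
        pid=study.pid,
        ein=ein,
        eout=eout,
        rwo=rwo,
        roi=study.roi.copy(),
        spacing=study.spacing,
    )


def save_maps(maps: PerfusionMaps, directory: str | Path) -> dict[str, str]:
    """Write the three maps as NIfTI files named {pid}_ein/_eout/_rwo."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(maps.spacing) + [1.0])
    paths = {}
    for name in ("ein", "eout", "rwo"):
        p = directory / f"{maps.pid}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(maps, name).astype(np.float64), affine), p)
        paths[name] = str(p)
    return paths
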