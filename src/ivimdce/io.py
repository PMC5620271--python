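"""NIfTI / CSV / JSON interchange.

Grids live in voxel space: the affine is diagonal with the voxel size,
no oblique orientations, 0-based indexing.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import Aif
from .simulate import DceSeries, DwiSeries


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_volume(data: np.ndarray, voxel_size, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), vs


def save_mask(mask: np.ndarray, voxel_size, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


def save_aif(aif: Aif, path: str | Path) -> None:
    pd.DataFrame({"time_s": aif.times, "cp_mM": aif.cp}).to_csv(path, index=False)


def load_aif(path: str | Path) -> Aif:
    df = pd.read_csv(path)
    return Aif(times=df["time_s"].to_numpy(float), cp=df["cp_mM"].to_numpy(float))


def save_subject(subject, out_dir: str | Path) -> None:
    """Write one simulated subject's acquisitions and mask as NIfTI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = subject.truth.voxel_size
    save_volume(subject.dwi.data, vs, out / "dwi_4d.nii.gz")
    save_volume(subject.dce.data, vs, out / "dce_4d.nii.gz")
    save_volume(subject.dce.pre_volume, vs, out / "precontrast_5deg.nii.gz")
    save_mask(subject.truth.roi_mask, vs, out / "roi_mask.nii.gz")
    subject.dwi.scheme.to_json(out / "dwi_scheme.json")
    subject.dce.scheme.to_json(out / "dce_scheme.json")


def load_dwi_series(dwi_path, scheme_path, voxel_size=None) -> DwiSeries:
    from .schemes import DwiScheme

    data, vs = load_volume(dwi_path)
    return DwiSeries(data=data, scheme=DwiScheme.from_json(scheme_path),
                     voxel_size=voxel_size or vs)


def load_dce_series(dce_path, pre_path, scheme_path, voxel_size=None) -> DceSeries:
    from .schemes import DceScheme

    data, vs = load_volume(dce_path)
    pre, _ = load_volume(pre_path)
    return DceSeries(data=data, pre_volume=pre,
                     scheme=DceScheme.from_json(scheme_path),
                     voxel_size=voxel_size or vs)
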