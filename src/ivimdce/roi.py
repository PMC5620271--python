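"""ROI summarization: parameter means, tumor volume, observer agreement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import FitError, ValidationError

#: Subjects with tumors below this volume are excluded upstream (mm³).
MIN_TUMOR_VOLUME = 30.0

#: Columns of the cohort table, in order.
SUBJECT_COLUMNS = (
    "subject_id", "stage_group", "ajcc_stage", "tumor_volume",
    "mean_D", "mean_f", "mean_Dstar",
    "mean_Ktrans", "mean_kep", "mean_ve", "mean_vp",
)


@dataclass
class SubjectRecord:
    """Per-subject ROI-mean parameters, tumor volume and stage."""

    subject_id: str
    stage_group: str
    ajcc_stage: str
    tumor_volume: float
    mean_D: float
    mean_f: float
    mean_Dstar: float
    mean_Ktrans: float
    mean_kep: float
    mean_ve: float
    mean_vp: float

    def __post_init__(self) -> None:
        low, high = {"I", "II"}, {"III", "IV"}
        if self.stage_group not in ("low", "high"):
            raise ValidationError(f"stage_group: unknown label {self.stage_group!r}")
        expect = low if self.stage_group == "low" else high
        if self.ajcc_stage not in expect:
            raise ValidationError(
                f"ajcc_stage: {self.ajcc_stage} inconsistent with "
                f"{self.stage_group} stage group"
            )
        if not self.tumor_volume > 0:
            raise ValidationError("tumor_volume: must be > 0")


def roi_mean(
    param_map: np.ndarray,
    roi_mask: np.ndarray,
    valid_mask: np.ndarray | None = None,
) -> tuple[float, int]:
    """Arithmetic mean of a parameter over the valid ROI voxels.

    Returns (mean, n_voxels).  Raises when no voxel is both inside the
    ROI and valid (the mean is undefined).
    """
    m = np.asarray(param_map, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != m.shape:
        raise ValidationError("roi_mask: shape mismatch with parameter map")
    sel = roi.copy()
    if valid_mask is not None:
        valid = np.asarray(valid_mask, dtype=bool)
        if valid.shape != m.shape:
            raise ValidationError("valid_mask: shape mismatch with parameter map")
        sel &= valid
    n = int(sel.sum())
    if n == 0:
        raise FitError("roi_mean undefined: no valid voxel inside the ROI")
    return float(m[sel].mean()), n


def tumor_volume(
    roi_mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> float:
    """Segmented tumor volume in mm³ (voxel count × voxel volume).

    An empty mask gives 0; the caller applies the small-tumor exclusion
    floor (MIN_TUMOR_VOLUME)."""
    if any(v <= 0 for v in voxel_size):
        raise ValidationError("voxel_size: must be positive")
    vv = float(np.prod(voxel_size))
    return float(np.asarray(roi_mask, dtype=bool).sum()) * vv


def median_dichotomize(obs1: np.ndarray, obs2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Default binning for agreement on continuous measurements:
    above/below the pooled median."""
    pooled = np.concatenate([obs1, obs2])
    med = np.median(pooled)
    return obs1 > med, obs2 > med


def agreement_kappa(
    measurements_obs1: np.ndarray,
    measurements_obs2: np.ndarray,
    binning=median_dichotomize,
) -> float:
    """Cohen's kappa between two observers' measurements.

    Continuous measurements are first categorized by ``binning``
    (default: dichotomization at the pooled median); pass
    ``binning=None`` if the inputs are already categories.
    """
    x = np.asarray(measurements_obs1)
    y = np.asarray(measurements_obs2)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("measurements: need paired 1-D arrays")
    if x.size < 2:
        raise ValidationError("measurements: need n >= 2 pairs")
    if binning is not None:
        x, y = binning(x, y)
    if np.unique(x).size < 2 and np.unique(y).size < 2:
        raise FitError("kappa undefined: both observers constant")
    return float(cohen_kappa_score(x, y))


def build_subject_record(
    subject_id: str,
    stage_group: str,
    ajcc_stage: str,
    roi_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    ivim_maps,
    tofts_maps,
) -> SubjectRecord:
    """Summarize one subject's fitted maps into a cohort-table row."""
    vol = tumor_volume(roi_mask, voxel_size)
    mean_D, _ = roi_mean(ivim_maps.D_map, roi_mask, ivim_maps.valid_mask)
    mean_f, _ = roi_mean(ivim_maps.f_map, roi_mask, ivim_maps.valid_mask)
    mean_Dstar, _ = roi_mean(ivim_maps.Dstar_map, roi_mask, ivim_maps.valid_mask)
    mean_Kt, _ = roi_mean(tofts_maps.Ktrans_map, roi_mask, tofts_maps.valid_mask)
    mean_kep, _ = roi_mean(tofts_maps.kep_map, roi_mask, tofts_maps.valid_mask)
    mean_ve, _ = roi_mean(tofts_maps.ve_map, roi_mask, tofts_maps.valid_mask)
    mean_vp, _ = roi_mean(tofts_maps.vp_map, roi_mask, tofts_maps.valid_mask)
    return SubjectRecord(
        subject_id=subject_id, stage_group=stage_group, ajcc_stage=ajcc_stage,
        tumor_volume=vol, mean_D=mean_D, mean_f=mean_f, mean_Dstar=mean_Dstar,
        mean_Ktrans=mean_Kt, mean_kep=mean_kep, mean_ve=mean_ve, mean_vp=mean_vp,
    )


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Cohort table with one row per subject (SUBJECT_COLUMNS order)."""
    return pd.DataFrame([{c: getattr(r, c) for c in SUBJECT_COLUMNS}
                         for r in records])
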