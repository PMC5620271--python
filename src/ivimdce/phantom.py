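"""Ground-truth digital phantoms.

A phantom is a small 3-D grid of voxels carrying true parameter maps
for both the IVIM diffusion model (D, f, D*) and the extended-Tofts
pharmacokinetic model (Ktrans, ve, vp), plus relaxometry (T10) and the
unweighted equilibrium signal S0.  An ellipsoidal "tumor" ROI is
embedded in homogeneous background tissue; within-tumor heterogeneity
is modelled as a log-normal perturbation of the per-subject means so
that voxel-level filtering and ROI averaging have realistic work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Parameters every phantom map set carries.
PARAM_NAMES = ("D", "f", "Dstar", "Ktrans", "ve", "vp", "T10", "S0")

#: Background (muscle-like) tissue defaults at 3 T.
BACKGROUND_TISSUE: dict[str, float] = {
    "D": 1.5e-3,     # mm²/s
    "f": 0.05,
    "Dstar": 20e-3,  # mm²/s
    "Ktrans": 0.10,  # 1/min
    "ve": 0.15,
    "vp": 0.02,
    "T10": 1000.0,   # ms
    "S0": 1000.0,
}

#: Tumor tissue defaults (low-stage nasopharyngeal carcinoma means).
TUMOR_TISSUE: dict[str, float] = {
    "D": 0.803e-3,
    "f": 0.157,
    "Dstar": 109.853e-3,
    "Ktrans": 0.645,
    "ve": 0.555,
    "vp": 0.088,
    "T10": 1400.0,
    "S0": 1000.0,
}

#: In-plane 230 mm FOV / 128 matrix ≈ 1.8 mm; 3 mm slices + 0.3 mm gap.
DEFAULT_VOXEL_SIZE: tuple[float, float, float] = (1.8, 1.8, 3.3)


@dataclass
class PhantomTruth:
    """Per-voxel ground truth for one subject.

    All maps share ``shape``; ``roi_mask`` marks the tumor.  kep is not
    stored — it is Ktrans/ve by model identity wherever needed.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    D_map: np.ndarray
    f_map: np.ndarray
    Dstar_map: np.ndarray
    Ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    T10_map: np.ndarray
    S0_map: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValidationError("shape: must be three positive integers")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size: must be three positive lengths")
        for name in PARAM_NAMES:
            m = np.asarray(getattr(self, f"{name}_map"), dtype=float)
            if m.shape != self.shape:
                raise ValidationError(f"{name}_map: shape {m.shape} != {self.shape}")
            setattr(self, f"{name}_map", m)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != self.shape:
            raise ValidationError("roi_mask: shape mismatch")
        self.validate()

    def validate(self) -> None:
        """Enforce physical invariants on every voxel."""
        checks = [
            ("D_map", self.D_map > 0, "D must be > 0"),
            ("f_map", (self.f_map >= 0) & (self.f_map < 1), "f must lie in [0, 1)"),
            ("Dstar_map", self.Dstar_map > self.D_map, "D* must exceed D"),
            ("Ktrans_map", self.Ktrans_map >= 0, "Ktrans must be >= 0"),
            ("ve_map", (self.ve_map >= 0) & (self.ve_map <= 1), "ve must lie in [0, 1]"),
            ("vp_map", (self.vp_map >= 0) & (self.vp_map < 1), "vp must lie in [0, 1)"),
            ("ve_map", self.ve_map + self.vp_map <= 1.0 + 1e-12, "ve + vp must be <= 1"),
            ("T10_map", self.T10_map > 0, "T10 must be > 0"),
            ("S0_map", self.S0_map >= 0, "S0 must be >= 0"),
        ]
        for name, ok, msg in checks:
            if not np.all(ok):
                raise ValidationError(f"{name}: {msg}")

    @property
    def kep_map(self) -> np.ndarray:
        """Reflux rate kep = Ktrans/ve, 1/min (NaN where ve == 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.ve_map > 0, self.Ktrans_map / self.ve_map, np.nan)

    def params_at(self, index: tuple[int, int, int]) -> dict[str, float]:
        return {name: float(getattr(self, f"{name}_map")[index]) for name in PARAM_NAMES}


def ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float] | None = None,
    semi_axes: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Boolean mask of the voxels whose centres fall inside an ellipsoid
    (voxel-index coordinates)."""
    shape = tuple(int(s) for s in shape)
    if center is None:
        center = tuple((s - 1) / 2 for s in shape)
    if semi_axes is None:
        semi_axes = tuple(max(s * 0.3, 1.0) for s in shape)
    if any(a <= 0 for a in semi_axes):
        raise ValidationError("semi_axes: must be positive")
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


# Hard physiological clip ranges applied after heterogeneity perturbation.
_CLIP = {
    "D": (1e-5, 3.5e-3),
    "f": (0.0, 0.95),
    "Dstar": (2e-3, 0.9),
    "Ktrans": (0.0, 5.0),
    "ve": (1e-3, 0.97),
    "vp": (0.0, 0.5),
    "T10": (100.0, 5000.0),
    "S0": (0.0, np.inf),
}


def generate_phantom(
    tumor_params: dict[str, float] | None = None,
    shape: tuple[int, int, int] = (16, 16, 8),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    background_params: dict[str, float] | None = None,
    tumor_cv: float = 0.10,
    semi_axes: tuple[float, float, float] | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> PhantomTruth:
    """Build a phantom with an ellipsoidal tumor in homogeneous background.

    Parameters
    ----------
    tumor_params : per-parameter tumor means (keys from PARAM_NAMES;
        missing keys fall back to TUMOR_TISSUE defaults).
    tumor_cv : within-tumor coefficient of variation; tumor voxels are
        drawn log-normally around the means (cv=0 gives a homogeneous
        tumor). T10 and S0 are perturbed too; background is homogeneous.
    semi_axes : ellipsoid semi-axes in voxels (default ~30% of grid).
    seed : seeds the heterogeneity draw; same seed, same truth.

    Returns
    -------
    PhantomTruth with ``roi_mask`` marking the tumor ellipsoid.
    """
    tp = dict(TUMOR_TISSUE)
    if tumor_params:
        unknown = set(tumor_params) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"tumor_params: unknown fields {sorted(unknown)}")
        tp.update(tumor_params)
    bp = dict(BACKGROUND_TISSUE)
    if background_params:
        unknown = set(background_params) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"background_params: unknown fields {sorted(unknown)}")
        bp.update(background_params)
    if tumor_cv < 0:
        raise ValidationError("tumor_cv: must be >= 0")
    _check_tissue("tumor_params", tp)
    _check_tissue("background_params", bp)

    roi = ellipsoid_mask(shape, semi_axes=semi_axes)
    rng = np.random.default_rng(seed)
    maps: dict[str, np.ndarray] = {}
    n_roi = int(roi.sum())
    for name in PARAM_NAMES:
        m = np.full(shape, bp[name], dtype=float)
        mean = tp[name]
        if tumor_cv > 0 and mean > 0:
            # log-normal with the requested mean and CV
            sigma = np.sqrt(np.log1p(tumor_cv**2))
            mu = np.log(mean) - sigma**2 / 2
            vals = rng.lognormal(mu, sigma, size=n_roi)
        else:
            vals = np.full(n_roi, mean)
        lo, hi = _CLIP[name]
        m[roi] = np.clip(vals, lo, hi)
        maps[name] = m
    # keep D* above D and ve+vp within the voxel
    maps["Dstar"] = np.maximum(maps["Dstar"], maps["D"] * 1.5)
    maps["vp"] = np.minimum(maps["vp"], 1.0 - maps["ve"] - 1e-6)
    maps["vp"] = np.maximum(maps["vp"], 0.0)

    return PhantomTruth(
        shape=tuple(shape),
        voxel_size=tuple(voxel_size),
        D_map=maps["D"],
        f_map=maps["f"],
        Dstar_map=maps["Dstar"],
        Ktrans_map=maps["Ktrans"],
        ve_map=maps["ve"],
        vp_map=maps["vp"],
        T10_map=maps["T10"],
        S0_map=maps["S0"],
        roi_mask=roi,
    )


def _check_tissue(label: str, p: dict[str, float]) -> None:
    if p["D"] <= 0:
        raise ValidationError(f"{label}.D: must be > 0")
    if not (0 <= p["f"] < 1):
        raise ValidationError(f"{label}.f: must lie in [0, 1)")
    if p["Dstar"] <= p["D"]:
        raise ValidationError(f"{label}.Dstar: must exceed D")
    if p["Ktrans"] < 0:
        raise ValidationError(f"{label}.Ktrans: must be >= 0")
    if not (0 <= p["ve"] <= 1):
        raise ValidationError(f"{label}.ve: must lie in [0, 1]")
    if not (0 <= p["vp"] < 1):
        raise ValidationError(f"{label}.vp: must lie in [0, 1)")
    if p["ve"] + p["vp"] > 1:
        raise ValidationError(f"{label}.ve: ve + vp must be <= 1")
    if p["T10"] <= 0:
        raise ValidationError(f"{label}.T10: must be > 0")
    if p["S0"] < 0:
        raise ValidationError(f"{label}.S0: must be >= 0")
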