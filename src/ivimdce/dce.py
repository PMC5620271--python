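"""Dynamic contrast-enhanced (DCE) pharmacokinetic modelling.

Pipeline per voxel:

1. two-point variable-flip-angle (VFA) T1 mapping from the 5°
   pre-contrast scan and the 15° pre-injection dynamics,
2. inversion of the spoiled-gradient-echo (SPGR) signal equation to an
   instantaneous T1(t) and, via the linear relaxivity relation
   R1(t) = R1(0) + r1·Ct(t), a tissue concentration curve Ct(t),
3. bounded nonlinear least-squares fit of the extended Tofts model

       Ct(t) = vp·Cp(t) + Ktrans · ∫₀ᵗ Cp(τ)·exp(−kep·(t−τ)) dτ

   against the arterial input function Cp, with kep = Ktrans/ve.

Ktrans and kep are reported in 1/min (the conventional unit); all
internal kinetics run in seconds with explicit conversion at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .aif import Aif
from .errors import FitError, ValidationError
from .schemes import DceScheme

#: fit bounds: Ktrans 1/min, ve fraction, vp fraction
TOFTS_BOUNDS_LO = (0.0, 1e-3, 0.0)
TOFTS_BOUNDS_HI = (5.0, 1.0, 0.5)
TOFTS_X0 = (0.3, 0.3, 0.05)

#: internal upsampling factor for the convolution quadrature
CONV_UPSAMPLE = 10


@dataclass
class T1Fit:
    """Two-point VFA result: pre-contrast T1 (ms) and equilibrium
    magnetization M0 (a.u.)."""

    T10: float
    M0: float
    valid: bool = True


@dataclass
class ToftsParams:
    """One voxel's fitted extended-Tofts parameters (Ktrans, kep in 1/min)."""

    Ktrans: float
    kep: float
    ve: float
    vp: float
    rss: float = 0.0
    converged: bool = True

    def validate(self) -> None:
        if self.Ktrans < 0:
            raise ValidationError("Ktrans: must be >= 0")
        # ve may be 0 only in the degenerate no-transfer model
        if not (0 < self.ve <= 1) and not (self.Ktrans == 0 and self.ve == 0):
            raise ValidationError("ve: must lie in (0, 1]")
        if not (0 <= self.vp < 1):
            raise ValidationError("vp: must lie in [0, 1)")
        if self.Ktrans > 0 and abs(self.kep * self.ve - self.Ktrans) > 1e-6 * self.Ktrans:
            raise ValidationError("kep: must equal Ktrans/ve")


@dataclass
class ToftsMaps:
    """Voxel-wise extended-Tofts maps with validity mask."""

    Ktrans_map: np.ndarray
    kep_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    T10_map: np.ndarray
    valid_mask: np.ndarray


def spgr_signal(M0, T1, TR: float, flip_deg: float):
    """Spoiled-gradient-echo steady-state signal.

    S = M0·sinα·(1−E1)/(1−E1·cosα), E1 = exp(−TR/T1); TR and T1 in the
    same unit (ms here).  Accepts scalars or broadcastable arrays.
    """
    M0 = np.asarray(M0, dtype=float)
    T1 = np.asarray(T1, dtype=float)
    if TR <= 0:
        raise ValidationError("TR: must be > 0")
    if not (0 < flip_deg < 90):
        raise ValidationError("flip_deg: must lie in (0, 90)")
    if np.any(T1 <= 0):
        raise ValidationError("T1: must be > 0")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-TR / T1)
    out = M0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
    return out if out.ndim else float(out)


def vfa_t1(
    S_pre, S_dyn_baseline, TR: float, flip_pre: float, flip_dyn: float
):
    """Two-point VFA T1/M0 estimate from signals at two flip angles.

    The SPGR equation is linear in (S/sinα, S/tanα) space:
    S/sinα = E1·(S/tanα) + M0·(1−E1); with two angles the slope E1 and
    intercept follow exactly.  A slope outside (0, 1) is non-physical
    (no T1 reproduces the signal pair) and flags the voxel invalid.

    Scalar inputs return a T1Fit; array inputs return (T10, M0, valid)
    arrays.
    """
    s1 = np.asarray(S_pre, dtype=float)
    s2 = np.asarray(S_dyn_baseline, dtype=float)
    scalar = s1.ndim == 0 and s2.ndim == 0
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        if scalar:
            return T1Fit(T10=np.nan, M0=np.nan, valid=False)
    a1, a2 = np.deg2rad(flip_pre), np.deg2rad(flip_dyn)
    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
        y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
        e1 = (y2 - y1) / (x2 - x1)
        m0 = (y1 - e1 * x1) / (1 - e1)
        t10 = np.where((e1 > 0) & (e1 < 1), -TR / np.log(np.where((e1 > 0) & (e1 < 1), e1, 0.5)), np.nan)
    valid = (s1 > 0) & (s2 > 0) & (e1 > 0) & (e1 < 1) & (m0 > 0) & np.isfinite(t10)
    t10 = np.where(valid, t10, np.nan)
    m0 = np.where(valid, m0, np.nan)
    if scalar:
        return T1Fit(T10=float(t10), M0=float(m0), valid=bool(valid))
    return t10, m0, valid


def signal_to_concentration(
    dyn_series: np.ndarray,
    t1fit: T1Fit,
    TR: float,
    flip_dyn: float,
    r1: float,
    baseline_dynamics: int = 7,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Convert one voxel's dynamic SPGR series to Gd concentration (mM).

    Inverts the SPGR equation per time point with M0 held at the VFA
    value, takes R1(t) = 1/T1(t) (1/s), and maps to concentration via
    Ct = (R1(t) − R1,baseline)/r1 — the linear relaxivity relation.
    The baseline-mean concentration is subtracted so pre-injection Ct
    averages exactly zero.

    Returns (Ct, point_valid, voxel_valid); the voxel is invalid when
    more than 20% of time points fail SPGR inversion (E1 outside (0,1)).
    """
    if r1 <= 0:
        raise ValidationError("r1: must be > 0")
    if baseline_dynamics < 1:
        raise ValidationError("baseline_dynamics: must be >= 1")
    s = np.asarray(dyn_series, dtype=float)
    if baseline_dynamics >= s.size:
        raise ValidationError("baseline_dynamics: must be < number of dynamics")
    if not t1fit.valid or not np.isfinite(t1fit.T10):
        return np.full_like(s, np.nan), np.zeros(s.shape, bool), False
    a = np.deg2rad(flip_dyn)
    msin = t1fit.M0 * np.sin(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (msin - s) / (msin - s * np.cos(a))
    ok = (e1 > 0) & (e1 < 1) & np.isfinite(e1)
    r1_t = np.full_like(s, np.nan)
    r1_t[ok] = -np.log(e1[ok]) / TR * 1000.0  # 1/s
    ct = np.full_like(s, np.nan)
    base = np.nanmean(r1_t[:baseline_dynamics]) if ok[:baseline_dynamics].any() else np.nan
    if np.isfinite(base):
        ct = (r1_t - base) / r1
    voxel_valid = bool(np.isfinite(base)) and (1 - ok.mean()) <= 0.20
    return ct, ok, voxel_valid


def exp_convolve(cp: np.ndarray, times: np.ndarray, kep_s: float,
                 upsample: int = CONV_UPSAMPLE) -> np.ndarray:
    """∫₀ᵗ Cp(τ)·exp(−kep·(t−τ)) dτ on the acquisition grid.

    Trapezoidal quadrature on a ``upsample``-times finer uniform grid
    (the dynamic interval of ~9 s is coarse relative to the bolus), run
    as the exact one-pole recursion

        I_k = e^{−kep·h}·I_{k−1} + (h/2)·(Cp_k + e^{−kep·h}·Cp_{k−1})

    which is unconditionally overflow-free for any kep ≥ 0.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(cp, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times: must be strictly increasing")
    if kep_s < 0:
        raise ValidationError("kep: must be >= 0")
    n_fine = (t.size - 1) * upsample + 1
    tf = np.linspace(t[0], t[-1], n_fine)
    cf = np.interp(tf, t, c)
    h = tf[1] - tf[0]
    e = np.exp(-kep_s * h)
    integ = lfilter([h / 2, e * h / 2], [1.0, -e], cf)
    # lfilter starts from y0 = (h/2)·Cp0; the true integral starts at 0 —
    # remove that spurious initial mass, propagated through the decay
    integ -= (h / 2) * cf[0] * np.exp(-kep_s * (tf - tf[0]))
    return integ[::upsample]


def extended_tofts_forward(
    params: ToftsParams, aif: Aif, times: np.ndarray | None = None,
    upsample: int = CONV_UPSAMPLE,
) -> np.ndarray:
    """Tissue concentration Ct(t) of the extended Tofts model (mM).

    ``times`` defaults to the AIF grid; Ktrans/kep are taken in 1/min
    and converted to 1/s internally.
    """
    params.validate()
    t = aif.times if times is None else np.asarray(times, dtype=float)
    if t.shape != aif.times.shape or not np.allclose(t, aif.times):
        raise ValidationError("times: must match the AIF time grid")
    return _tofts_ct(aif.cp, t, params.Ktrans, params.ve, params.vp, upsample)


def _tofts_ct(cp, times, ktrans_min, ve, vp, upsample=CONV_UPSAMPLE):
    if ktrans_min == 0:
        return vp * np.asarray(cp, dtype=float)
    kep_s = (ktrans_min / ve) / 60.0
    integ = exp_convolve(cp, times, kep_s, upsample)
    return vp * np.asarray(cp, dtype=float) + (ktrans_min / 60.0) * integ


def fit_extended_tofts(
    ct: np.ndarray,
    aif: Aif,
    times: np.ndarray | None = None,
    x0: tuple[float, float, float] = TOFTS_X0,
    upsample: int = CONV_UPSAMPLE,
) -> ToftsParams:
    """Bounded least-squares fit of (Ktrans, ve, vp) to one voxel's Ct.

    kep is reported as Ktrans/ve.  A flat, zero or non-enhancing curve
    is non-physiological and comes back with ``converged=False`` (such
    voxels are excluded from maps, mirroring the "any unphysiological
    data such as zero were excluded" rule).
    """
    t = aif.times if times is None else np.asarray(times, dtype=float)
    c = np.asarray(ct, dtype=float)
    if c.shape != t.shape:
        raise ValidationError("ct: length must match the time grid")
    if not np.all(np.isfinite(c)):
        return ToftsParams(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    if c.size < 10:
        raise ValidationError("ct: need at least 10 time points")
    # unphysiological: no enhancement at all
    if np.nanmax(np.abs(c)) < 1e-9 or np.nanmax(c) <= 0:
        return ToftsParams(0.0, np.nan, np.nan, 0.0, float(np.sum(c**2)), False)

    def resid(x):
        kt, ve, vp = x
        return _tofts_ct(aif.cp, t, kt, ve, vp, upsample) - c

    try:
        res = least_squares(
            resid, x0=x0, bounds=(TOFTS_BOUNDS_LO, TOFTS_BOUNDS_HI),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except Exception:
        return ToftsParams(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    kt, ve, vp = (float(v) for v in res.x)
    converged = bool(res.success) and kt > 1e-9  # Ktrans pinned at zero ⇒ unphysiological
    return ToftsParams(
        Ktrans=kt, kep=kt / ve, ve=ve, vp=vp,
        rss=float(2 * res.cost), converged=converged,
    )


def fit_dce_map(
    dce4d: np.ndarray,
    pre_volume: np.ndarray,
    roi_mask: np.ndarray,
    aif: Aif,
    scheme: DceScheme,
    upsample: int = CONV_UPSAMPLE,
) -> ToftsMaps:
    """Full per-voxel DCE pipeline over an ROI.

    VFA T1 from the pre-contrast volume and the pre-injection dynamic
    baseline, SPGR inversion to concentration, then the extended-Tofts
    fit.  ``valid_mask`` records every exclusion (failed T1, failed
    inversion, non-convergence, zero enhancement).
    """
    data = np.asarray(dce4d, dtype=float)
    if data.ndim != 4:
        raise ValidationError("dce4d: expected a 4-D (x,y,z,t) array")
    if data.shape[3] != scheme.n_dynamics:
        raise ValidationError(
            f"dce4d: {data.shape[3]} dynamics but scheme has {scheme.n_dynamics}"
        )
    pre = np.asarray(pre_volume, dtype=float)
    if pre.shape != data.shape[:3]:
        raise ValidationError("pre_volume: shape mismatch with dynamic grid")
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != data.shape[:3]:
        raise ValidationError("roi_mask: shape mismatch")
    if not roi.any():
        raise FitError("empty ROI: nothing to fit")

    nb = scheme.n_baseline
    shape = data.shape[:3]
    kt_map = np.full(shape, np.nan)
    kep_map = np.full(shape, np.nan)
    ve_map = np.full(shape, np.nan)
    vp_map = np.full(shape, np.nan)
    t10_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    for idx in zip(*np.nonzero(roi)):
        series = data[idx]
        baseline = float(series[:nb].mean())
        t1 = vfa_t1(float(pre[idx]), baseline, scheme.TR,
                    scheme.flip_pre, scheme.flip_dyn)
        if not t1.valid:
            continue
        ct, _, vox_ok = signal_to_concentration(
            series, t1, scheme.TR, scheme.flip_dyn, scheme.r1,
            baseline_dynamics=nb,
        )
        if not vox_ok:
            continue
        ct = np.nan_to_num(ct, nan=0.0)
        fit = fit_extended_tofts(ct, aif, upsample=upsample)
        if not fit.converged:
            continue
        kt_map[idx] = fit.Ktrans
        kep_map[idx] = fit.kep
        ve_map[idx] = fit.ve
        vp_map[idx] = fit.vp
        t10_map[idx] = t1.T10
        valid[idx] = True

    return ToftsMaps(Ktrans_map=kt_map, kep_map=kep_map, ve_map=ve_map,
                     vp_map=vp_map, T10_map=t10_map, valid_mask=valid)
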