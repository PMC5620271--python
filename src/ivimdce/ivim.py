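"""Intravoxel-incoherent-motion (IVIM) bi-exponential model and fitting.

The voxel signal over b-values follows

    S(b) = S0 · [(1 − f)·exp(−b·D) + f·exp(−b·(D + D*))]

with D the true molecular diffusion coefficient (mm²/s), f the
perfusion fraction of the microvascular compartment and D* the
pseudodiffusion coefficient (mm²/s, ≫ D).

Fitting is segmented, the standard two-stage estimator: D is first
obtained from a log-linear fit restricted to high b-values (b > 200
s/mm² by default) where the perfusion term has decayed away, then f
and D* are estimated by bounded nonlinear least squares over *all*
b-values with D held fixed.  Voxels whose unweighted signal is not
safely above the noise floor are excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .schemes import DwiScheme

#: Upper bound on the pseudodiffusion coefficient, mm²/s.
DSTAR_MAX = 1.0


@dataclass
class IvimParams:
    """One voxel's fitted IVIM parameters."""

    D: float
    f: float
    Dstar: float
    S0: float
    rss: float = 0.0
    converged: bool = True

    def validate(self) -> None:
        if self.D <= 0:
            raise ValidationError("D: must be > 0")
        if not (0 <= self.f <= 1):
            raise ValidationError("f: must lie in [0, 1]")
        if self.Dstar < self.D:
            raise ValidationError("Dstar: must be >= D")
        if self.rss < 0:
            raise ValidationError("rss: must be >= 0")


@dataclass
class IvimMaps:
    """Voxel-wise IVIM parameter maps with a validity mask.

    Parameters are defined (non-NaN) only where ``valid_mask`` is true:
    the voxel passed the SNR filter, kept positive high-b signals and
    the perfusion stage converged.
    """

    D_map: np.ndarray
    f_map: np.ndarray
    Dstar_map: np.ndarray
    valid_mask: np.ndarray


def ivim_forward(params: IvimParams, b_values: np.ndarray) -> np.ndarray:
    """Evaluate the bi-exponential IVIM signal at the given b-values."""
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValidationError("b_values: must be >= 0")
    params.validate()
    return ivim_signal(b, params.S0, params.D, params.f, params.Dstar)


def ivim_signal(
    b: np.ndarray, S0: float, D: float, f: float, Dstar: float
) -> np.ndarray:
    """Raw bi-exponential evaluation (no validation; used in hot loops)."""
    return S0 * ((1.0 - f) * np.exp(-b * D) + f * np.exp(-b * (D + Dstar)))


def fit_high_b_mono(
    signals: np.ndarray,
    b_values: np.ndarray,
    b_threshold: float = 200.0,
) -> tuple[float, float]:
    """Mono-exponential log-linear stage: D from b-values above threshold.

    Ordinary least squares of ln S on b restricted to b strictly
    greater than ``b_threshold``; returns (D, log-intercept) where
    D = −slope.

    Raises
    ------
    FitError if fewer than two b-values exceed the threshold
    (a configuration error) or if any included signal is non-positive
    (log undefined; the caller marks the voxel invalid).
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    sel = b > b_threshold
    if sel.sum() < 2:
        raise FitError(
            f"b_threshold={b_threshold}: fewer than 2 b-values above threshold"
        )
    if np.any(s[sel] <= 0):
        raise FitError("non-positive signal at an included high b-value")
    slope, intercept = np.polyfit(b[sel], np.log(s[sel]), 1)
    return -float(slope), float(intercept)


def fit_perfusion(
    signals: np.ndarray,
    b_values: np.ndarray,
    D_fixed: float,
    log_intercept: float | None = None,
    refine_D: bool = False,
) -> IvimParams:
    """Perfusion stage: (f, D*, S0) by bounded least squares, D fixed.

    Warm start: f₀ from the high-b intercept (the extrapolated
    mono-exponential underestimates S(0) by exactly the perfusion
    fraction), clipped to [0.01, 0.5]; D*₀ = 10·D.

    With ``refine_D`` the diffusion coefficient is re-estimated jointly
    in the nonlinear stage (off by default; the classic segmented fit
    keeps D at its log-linear value).

    Non-convergence is reported through ``converged=False``, never as
    an exception.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if D_fixed <= 0:
        raise ValidationError("D_fixed: must be > 0")
    if not np.all(np.isfinite(s)):
        raise ValidationError("signals: must be finite")

    s_b0 = float(s[np.argmin(b)])
    if log_intercept is not None and s_b0 > 0:
        f0 = float(np.clip(1.0 - np.exp(log_intercept) / s_b0, 0.01, 0.5))
    else:
        f0 = 0.1
    d0 = float(np.clip(10.0 * D_fixed, D_fixed * 1.01, DSTAR_MAX))
    s0_0 = max(s_b0, 1e-12)

    if refine_D:
        def resid(x):
            f, dstar, s0, d = x
            return ivim_signal(b, s0, d, f, dstar) - s
        x0 = (f0, d0, s0_0, D_fixed)
        lo = (0.0, D_fixed * 1e-3, 0.0, 1e-6)
        hi = (1.0, DSTAR_MAX, np.inf, 1e-1)
    else:
        def resid(x):
            f, dstar, s0 = x
            return ivim_signal(b, s0, D_fixed, f, dstar) - s
        x0 = (f0, d0, s0_0)
        lo = (0.0, D_fixed, 0.0)
        hi = (1.0, DSTAR_MAX, np.inf)

    try:
        res = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception:
        return IvimParams(D=D_fixed, f=np.nan, Dstar=np.nan, S0=np.nan,
                          rss=np.inf, converged=False)
    f_hat, dstar_hat, s0_hat = res.x[:3]
    d_hat = res.x[3] if refine_D else D_fixed
    return IvimParams(
        D=float(d_hat),
        f=float(f_hat),
        Dstar=float(dstar_hat),
        S0=float(s0_hat),
        rss=float(2 * res.cost),
        converged=bool(res.success),
    )


def fit_ivim_voxel(
    signals: np.ndarray,
    b_values: np.ndarray,
    b_threshold: float = 200.0,
    refine_D: bool = False,
) -> IvimParams | None:
    """Full segmented fit for one voxel; None if the voxel is unusable
    (non-positive high-b signal or non-positive D estimate)."""
    try:
        D, logint = fit_high_b_mono(signals, b_values, b_threshold)
    except FitError as exc:
        if "fewer than 2" in str(exc):
            raise
        return None
    if D <= 0:
        return None
    return fit_perfusion(signals, b_values, D, log_intercept=logint,
                         refine_D=refine_D)


def snr_valid_mask(
    b0_volume: np.ndarray, noise_sigma: float, k: float = 5.0
) -> np.ndarray:
    """Voxels whose unweighted (b=0) signal clears k·sigma.

    This is the "safely above background noise" filter: with magnitude
    (Rician) noise, background voxels rarely exceed ~5σ, so k=5 keeps
    essentially only true signal.
    """
    if noise_sigma <= 0:
        raise ValidationError("noise_sigma: must be > 0")
    if k < 0:
        raise ValidationError("k: must be >= 0")
    return np.asarray(b0_volume, dtype=float) >= k * noise_sigma


def average_directions(data5d: np.ndarray) -> np.ndarray:
    """Average a (x, y, z, b, direction) series over its direction axis.

    Diffusion is modelled as isotropic, so orthogonal directions are
    interchangeable and averaging only improves SNR.
    """
    d = np.asarray(data5d, dtype=float)
    if d.ndim != 5:
        raise ValidationError("data5d: expected a 5-D (x,y,z,b,dir) array")
    return d.mean(axis=4)


def fit_ivim_map(
    data4d: np.ndarray,
    scheme: DwiScheme,
    roi_mask: np.ndarray,
    noise_sigma: float | None = None,
    snr_k: float = 5.0,
    b_threshold: float = 200.0,
    refine_D: bool = False,
) -> IvimMaps:
    """Segmented IVIM fit over every ROI voxel of a 4-D (x,y,z,b) series.

    ``valid_mask`` is the conjunction of the SNR filter (skipped when
    ``noise_sigma`` is None), positive-signal/positive-D checks and
    perfusion-stage convergence.  Maps hold NaN outside the valid set.
    """
    data = np.asarray(data4d, dtype=float)
    if data.ndim != 4:
        raise ValidationError("data4d: expected a 4-D (x,y,z,b) array")
    if data.shape[3] != scheme.n_b:
        raise ValidationError(
            f"data4d: {data.shape[3]} volumes but scheme has {scheme.n_b} b-values"
        )
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != data.shape[:3]:
        raise ValidationError("roi_mask: shape mismatch with series grid")
    if not roi.any():
        raise FitError("empty ROI: nothing to fit")

    b = np.asarray(scheme.b_values, dtype=float)
    candidates = roi.copy()
    if noise_sigma is not None:
        candidates &= snr_valid_mask(data[..., 0], noise_sigma, snr_k)

    shape = data.shape[:3]
    D_map = np.full(shape, np.nan)
    f_map = np.full(shape, np.nan)
    Dstar_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    for idx in zip(*np.nonzero(candidates)):
        fit = fit_ivim_voxel(data[idx], b, b_threshold=b_threshold,
                             refine_D=refine_D)
        if fit is None or not fit.converged:
            continue
        D_map[idx] = fit.D
        f_map[idx] = fit.f
        Dstar_map[idx] = fit.Dstar
        valid[idx] = True

    return IvimMaps(D_map=D_map, f_map=f_map, Dstar_map=Dstar_map,
                    valid_mask=valid)
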