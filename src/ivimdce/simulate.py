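"""Forward simulation of noisy DWI and DCE acquisitions from a phantom.

The diffusion series is the bi-exponential IVIM forward model under
Rician noise (magnitude MRI); the dynamic series is the extended-Tofts
tissue concentration pushed through the linear relaxivity relation and
the spoiled-gradient-echo signal equation, under Gaussian noise (the
enhanced dynamics are high-SNR, where Rician ≈ Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aif import Aif
from .dce import _tofts_ct, spgr_signal
from .errors import ValidationError
from .ivim import ivim_signal
from .phantom import PhantomTruth
from .schemes import DceScheme, DwiScheme


@dataclass
class DwiSeries:
    """4-D (x, y, z, b) diffusion series with its scheme."""

    data: np.ndarray
    scheme: DwiScheme
    voxel_size: tuple[float, float, float]


@dataclass
class DceSeries:
    """4-D (x, y, z, t) dynamic series plus the low-flip pre-contrast
    volume, with the acquisition scheme."""

    data: np.ndarray
    pre_volume: np.ndarray
    scheme: DceScheme
    voxel_size: tuple[float, float, float]


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude of the signal after complex Gaussian noise of scale sigma."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


def simulate_dwi(
    truth: PhantomTruth,
    scheme: DwiScheme,
    noise_sigma: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
    n_directions: int = 3,
) -> DwiSeries:
    """Simulate the direction-averaged multi-b diffusion series.

    Each voxel follows S(b) = S0·[(1−f)e^{−bD} + f·e^{−b(D+D*)}].  The
    stored series emulates the clinical protocol: magnitude (Rician)
    images from ``n_directions`` orthogonal diffusion directions ×
    ``scheme.n_averages`` signal averages, averaged voxel-wise, so its
    effective noise SD is noise_sigma/√(n_directions·n_averages).
    ``noise_sigma`` is the per-image noise scale; 0 returns the exact
    forward model.  The Rician background floor (mean σ·√(π/2) where
    the true signal is zero) survives magnitude-domain averaging.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma: must be >= 0")
    if n_directions < 1:
        raise ValidationError("n_directions: must be >= 1")
    b = np.asarray(scheme.b_values, dtype=float)
    clean = ivim_signal(
        b[None, None, None, :],
        truth.S0_map[..., None],
        truth.D_map[..., None],
        truth.f_map[..., None],
        truth.Dstar_map[..., None],
    )
    if noise_sigma == 0:
        data = clean
    else:
        rng = np.random.default_rng(seed)
        n_rep = n_directions * scheme.n_averages
        data = np.zeros_like(clean)
        for _ in range(n_rep):
            data += add_rician_noise(clean, noise_sigma, rng)
        data /= n_rep
    return DwiSeries(data=data, scheme=scheme, voxel_size=truth.voxel_size)


def effective_dwi_sigma(scheme: DwiScheme, noise_sigma: float,
                        n_directions: int = 3) -> float:
    """Noise SD of the stored (averaged) diffusion series."""
    return noise_sigma / np.sqrt(n_directions * scheme.n_averages)


def simulate_dce(
    truth: PhantomTruth,
    scheme: DceScheme,
    aif: Aif,
    noise_sigma: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> DceSeries:
    """Simulate the dynamic SPGR series and the pre-contrast volume.

    Per voxel: Ct(t) from the extended Tofts model, instantaneous
    R1(t) = 1/T10 + r1·Ct(t), SPGR signal at the dynamic flip angle,
    plus a separate pre-contrast volume at the low flip angle.
    Gaussian noise of scale ``noise_sigma`` is added to both.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma: must be >= 0")
    if aif.times.size != scheme.n_dynamics:
        raise ValidationError("aif: time grid must match the scheme dynamics")
    t = scheme.times
    shape = truth.shape
    n_t = scheme.n_dynamics

    # Tofts forward per voxel; kep varies continuously so voxels are
    # evaluated individually (grids are small by design).
    ct = np.zeros(shape + (n_t,), dtype=float)
    kt = truth.Ktrans_map
    ve = truth.ve_map
    vp = truth.vp_map
    it = np.nditer(kt, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        ct[idx] = _tofts_ct(aif.cp, t, float(kt[idx]), float(ve[idx]), float(vp[idx]))

    r1_t = 1000.0 / truth.T10_map[..., None] + scheme.r1 * ct  # 1/s
    if np.any(r1_t <= 0):
        raise ValidationError("T10_map: nonphysical T1 during enhancement")
    t1_ms = 1000.0 / r1_t
    dyn = spgr_signal(truth.S0_map[..., None], t1_ms, scheme.TR, scheme.flip_dyn)
    pre = spgr_signal(truth.S0_map, truth.T10_map, scheme.TR, scheme.flip_pre)

    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        dyn = dyn + rng.normal(0.0, noise_sigma, size=dyn.shape)
        pre = pre + rng.normal(0.0, noise_sigma, size=pre.shape)
    return DceSeries(data=dyn, pre_volume=np.asarray(pre, dtype=float),
                     scheme=scheme, voxel_size=truth.voxel_size)
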