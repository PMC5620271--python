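"""Arterial input function (AIF) synthesis.

A measured patient AIF (e.g. from the vertebral artery) is not
available for synthetic cohorts, so the package generates a
population-average bolus of the Parker form — two Gaussians for the
first and second pass plus a sigmoid-modulated exponential washout —
expressed directly as plasma concentration and time-shifted so that
the bolus starts at the injection dynamic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .schemes import DceScheme

# Population-average bolus shape parameters (time unit: minutes).
_A = (0.809, 0.330)        # mM·min, Gaussian areas
_T = (0.17046, 0.365)      # min, Gaussian centres
_SIG = (0.0563, 0.132)     # min, Gaussian widths
_ALPHA = 1.050             # mM, washout amplitude
_BETA = 0.1685             # 1/min, washout rate
_S = 38.078                # 1/min, sigmoid steepness
_TAU = 0.483               # min, sigmoid centre


@dataclass(frozen=True)
class Aif:
    """Plasma contrast concentration cp(t) on an explicit time grid.

    times in s from series start; cp in mM. cp must be zero before the
    bolus, non-negative and finite.
    """

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValidationError("times/cp: must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times: must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValidationError("cp: must be finite")
        if np.any(c < 0):
            raise ValidationError("cp: must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cp", c)


def parker_cp(t_s: np.ndarray) -> np.ndarray:
    """Population bolus plasma concentration at times ``t_s`` (s) after
    bolus arrival; zero for t ≤ 0."""
    t = np.asarray(t_s, dtype=float) / 60.0  # minutes
    cp = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out = np.zeros_like(tp)
    for a, mu, sig in zip(_A, _T, _SIG):
        out += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((tp - mu) ** 2) / (2 * sig**2))
    out += _ALPHA * np.exp(-_BETA * tp) / (1 + np.exp(-_S * (tp - _TAU)))
    cp[pos] = out
    return cp


def population_aif(scheme: DceScheme) -> Aif:
    """Population AIF sampled on the scheme's dynamic time grid.

    cp is exactly zero at and before the injection dynamic (contrast is
    administered *at* that acquisition, so its signal is still
    pre-contrast), then follows the population bolus.
    """
    t = scheme.times
    cp = parker_cp(t - scheme.injection_time)
    return Aif(times=t, cp=cp)
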