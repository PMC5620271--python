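"""Two-group synthetic cohorts for staging analyses.

Subjects belong to a low (AJCC I–II) or high (III–IV) stage group.
Per-subject ROI-mean true parameters are drawn from group-specific
truncated-normal marginals (defaults: the published group means/SDs of
a 75-patient nasopharyngeal-carcinoma cohort, 29 low / 46 high), with
a Gaussian-copula single-factor structure inducing a controllable
Spearman correlation between the perfusion-related IVIM parameters
(f, D*) and the DCE parameters (Ktrans, vp positively; ve negatively).
kep is never sampled: it is Ktrans/ve by model identity.

Each subject then gets a phantom (per-subject means + within-tumor
log-normal heterogeneity) and simulated noisy DWI and DCE series, so
the whole imaging pipeline can run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .aif import Aif, population_aif
from .errors import ValidationError
from .phantom import PhantomTruth, generate_phantom
from .schemes import DceScheme, DwiScheme
from .simulate import (
    DceSeries,
    DwiSeries,
    effective_dwi_sigma,
    simulate_dce,
    simulate_dwi,
)

#: Parameters with an explicit group distribution (kep is derived).
SAMPLED_PARAMS = ("D", "f", "Dstar", "Ktrans", "ve", "vp")

#: Copula factor loadings' signs: ve moves opposite to the perfusion set.
_LOADING_SIGN = {"D": 0.0, "f": 1.0, "Dstar": 1.0, "Ktrans": 1.0,
                 "ve": -1.0, "vp": 1.0}

#: Truncation ranges of the per-subject ROI-mean marginals.
_TRUNC = {
    "D": (0.2e-3, 2.5e-3),
    "f": (0.005, 0.6),
    "Dstar": (5e-3, 0.45),
    "Ktrans": (0.05, 2.0),
    "ve": (0.05, 0.95),
    "vp": (0.002, 0.3),
}

#: Published group means ± SD (low stage n=29, high stage n=46):
#: D, D* in mm²/s; Ktrans, kep in 1/min; f, ve, vp fractions.
#: kep is reference-only (derived as Ktrans/ve when sampling).
LOW_STAGE_PARAMS: dict[str, tuple[float, float]] = {
    "D": (0.803e-3, 0.188e-3),
    "f": (0.157, 0.096),
    "Dstar": (109.853e-3, 63.651e-3),
    "Ktrans": (0.645, 0.102),
    "kep": (0.885, 0.213),
    "ve": (0.555, 0.311),
    "vp": (0.088, 0.077),
}
HIGH_STAGE_PARAMS: dict[str, tuple[float, float]] = {
    "D": (0.700e-3, 0.193e-3),
    "f": (0.130, 0.114),
    "Dstar": (98.686e-3, 64.372e-3),
    "Ktrans": (0.511, 0.137),
    "kep": (0.748, 0.227),
    "ve": (0.869, 0.631),
    "vp": (0.065, 0.069),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a two-group cohort.

    cross_correlation is the target pairwise Spearman correlation
    among the correlated parameter set (|rho| < 1); noise_sigma is the
    DWI magnitude noise SD in S0 units (the DCE noise is scaled to the
    same baseline SNR); shape/semi-axes control the per-subject grids.
    """

    n_low: int = 29
    n_high: int = 46
    group_params: dict = field(default_factory=lambda: {
        "low": LOW_STAGE_PARAMS, "high": HIGH_STAGE_PARAMS})
    cross_correlation: float = 0.5
    noise_sigma: float = 20.0
    seed: int = 0
    shape: tuple[int, int, int] = (12, 12, 6)
    tumor_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValidationError("n_low/n_high: counts must be > 0")
        if not (abs(self.cross_correlation) < 1):
            raise ValidationError(
                "cross_correlation: |rho| must be < 1 (correlation matrix "
                "infeasible for the pair (f, Ktrans) otherwise)"
            )
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma: must be >= 0")
        for grp in ("low", "high"):
            params = self.group_params[grp]
            for name in SAMPLED_PARAMS:
                mean, sd = params[name]
                lo, hi = _TRUNC[name]
                if not (lo <= mean <= hi):
                    raise ValidationError(
                        f"group_params[{grp}][{name}]: mean {mean} outside "
                        f"valid range [{lo}, {hi}]"
                    )
                if sd < 0:
                    raise ValidationError(
                        f"group_params[{grp}][{name}]: sd must be >= 0")


@dataclass
class SubjectData:
    """One simulated subject: identity, truth and acquisitions."""

    subject_id: str
    stage_group: str           # "low" | "high"
    ajcc_stage: str            # "I".."IV"
    truth: PhantomTruth
    true_means: dict[str, float]
    dwi: DwiSeries
    dce: DceSeries


def sample_subject_means(
    spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-subject true ROI-mean parameters for the whole cohort.

    Gaussian copula with one latent factor: in z-space each correlated
    parameter loads ±√r on a shared factor, where r = 2·sin(π·ρ/6)
    converts the requested Spearman rho to the Gaussian (Pearson)
    correlation; the marginals are truncated normals, whose monotone
    quantile transform preserves ranks exactly.
    """
    rho = spec.cross_correlation
    r = 2.0 * np.sin(np.pi * rho / 6.0)  # Spearman -> Gaussian Pearson
    a = np.sqrt(abs(r))
    sign_r = 1.0 if r >= 0 else -1.0
    # loadings: the IVIM perfusion block (f, D*) keeps +a; the DCE block
    # takes sign(rho)·a (ve opposite), so cross-block pairs get the
    # requested signed correlation and within-block pairs stay positive.
    ivim_block = {"f", "Dstar"}
    loadings = {
        name: (s * a if name in ivim_block else s * a * sign_r)
        for name, s in _LOADING_SIGN.items()
    }

    rows = []
    counts = {"low": spec.n_low, "high": spec.n_high}
    stages = {"low": ("I", "II"), "high": ("III", "IV")}
    sid = 0
    for grp in ("low", "high"):
        n = counts[grp]
        params = spec.group_params[grp]
        g = rng.standard_normal(n)  # shared latent factor
        z = {}
        for name in SAMPLED_PARAMS:
            eps = rng.standard_normal(n)
            load = loadings[name]
            if load == 0 or r == 0:
                z[name] = eps
            else:
                z[name] = load * g + np.sqrt(1 - a**2) * eps
        x = {}
        for name in SAMPLED_PARAMS:
            mean, sd = params[name]
            lo, hi = _TRUNC[name]
            if sd == 0:
                x[name] = np.full(n, mean)
            else:
                aa, bb = (lo - mean) / sd, (hi - mean) / sd
                u = norm.cdf(z[name])
                x[name] = truncnorm.ppf(u, aa, bb, loc=mean, scale=sd)
        # keep ve + vp physical
        x["vp"] = np.minimum(x["vp"], 1.0 - x["ve"] - 1e-6)
        for i in range(n):
            rows.append({
                "subject_id": f"sub-{sid:03d}",
                "stage_group": grp,
                "ajcc_stage": stages[grp][i % 2],
                **{name: float(x[name][i]) for name in SAMPLED_PARAMS},
                "kep": float(x["Ktrans"][i] / x["ve"][i]),
            })
            sid += 1
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    dwi_scheme: DwiScheme | None = None,
    dce_scheme: DceScheme | None = None,
    aif: Aif | None = None,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate every subject of the cohort.

    Returns the list of subject datasets (phantom truth + noisy DWI and
    DCE series) and the ground-truth subject table (one row per
    subject, the generative ROI means).  Fully deterministic given
    ``spec.seed``.
    """
    dwi_scheme = dwi_scheme or DwiScheme()
    dce_scheme = dce_scheme or DceScheme()
    aif = aif or population_aif(dce_scheme)

    ss = np.random.SeedSequence(spec.seed)
    means_seed, *subj_seeds = ss.spawn(1 + spec.n_low + spec.n_high)
    truth_table = sample_subject_means(spec, np.random.default_rng(means_seed))

    # DCE noise scaled so both series share the baseline SNR (see docs)
    subjects: list[SubjectData] = []
    for (_, row), sseq in zip(truth_table.iterrows(), subj_seeds):
        tumor = {name: row[name] for name in SAMPLED_PARAMS}
        s_phantom, s_dwi, s_dce = sseq.spawn(3)
        # randomize tumor extent a little so volumes vary
        rng = np.random.default_rng(s_phantom)
        semi = tuple(
            float(np.clip(0.30 * s * rng.uniform(0.75, 1.25), 1.0, s / 2))
            for s in spec.shape
        )
        truth = generate_phantom(
            tumor_params=tumor, shape=spec.shape, tumor_cv=spec.tumor_cv,
            semi_axes=semi, seed=s_phantom,
        )
        dwi = simulate_dwi(truth, dwi_scheme, spec.noise_sigma, seed=s_dwi)
        # DCE noise matched to the *stored* (averaged) DWI baseline SNR
        s0_ref = float(np.median(truth.S0_map[truth.roi_mask]))
        sigma_eff = effective_dwi_sigma(dwi_scheme, spec.noise_sigma)
        dce_sigma = sigma_eff * _dce_baseline_scale(truth, dce_scheme) / max(s0_ref, 1e-12)
        dce = simulate_dce(truth, dce_scheme, aif, dce_sigma, seed=s_dce)
        subjects.append(SubjectData(
            subject_id=row["subject_id"],
            stage_group=row["stage_group"],
            ajcc_stage=row["ajcc_stage"],
            truth=truth,
            true_means={**tumor, "kep": float(row["kep"])},
            dwi=dwi,
            dce=dce,
        ))
    return subjects, truth_table


def _dce_baseline_scale(truth: PhantomTruth, scheme: DceScheme) -> float:
    """Median pre-injection dynamic signal inside the ROI (noise anchor)."""
    from .dce import spgr_signal

    s = spgr_signal(truth.S0_map[truth.roi_mask], truth.T10_map[truth.roi_mask],
                    scheme.TR, scheme.flip_dyn)
    return float(np.median(s))
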