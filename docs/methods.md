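# Methods

This note documents the models, the synthetic-data design, the
numerical choices and the limitations of the package. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal models

### IVIM diffusion

Voxel signal over diffusion weighting b (s/mm²):

    S(b) = S0 · [(1 − f)·exp(−b·D) + f·exp(−b·(D + D*))]

- `D` — true (molecular) diffusion coefficient, mm²/s; tissue
  cellularity marker. Typical NPC values ≈ 0.7–0.8 × 10⁻³.
- `f` — perfusion fraction (dimensionless, [0, 1)); the fraction of
  voxel signal from the microvascular compartment.
- `D*` — pseudodiffusion coefficient, mm²/s; apparent diffusion of
  blood in the capillary network, one to two orders above `D`.

The default acquisition is the 13-b protocol
(0, 10, 20, 30, 40, 60, 100, 120, 160, 200, 300, 500, 1000 s/mm²),
three orthogonal diffusion directions averaged, three signal averages.

**Segmented fit.** Stage 1 estimates `D` by ordinary least squares of
ln S on b restricted to b **strictly greater than** 200 s/mm²
(b ∈ {300, 500, 1000} by default; the threshold is configurable since
the literature varies). Stage 2 estimates (f, D*, S0) over all
b-values by bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective) with `D` held fixed — the classic segmented
estimator; a joint-refinement option (`refine_D`) re-estimates `D` in
stage 2 behind a flag. Damped least squares with box bounds was chosen
over an unbounded Levenberg–Marquardt because the bounds
(f ∈ [0, 1], D* ∈ [D, 1.0] mm²/s) are part of the estimator contract.

Initialisation is deterministic: f₀ = 1 − exp(stage-1 intercept)/S(0)
clipped to [0.01, 0.5] (the extrapolated mono-exponential
underestimates S(0) by exactly the perfusion fraction), D*₀ = 10·D.
Convergence tolerances 1e-12; non-convergence marks the voxel invalid
rather than raising.

**SNR filter.** Only voxels with S(b=0) ≥ k·σ are fitted (default
k = 5; σ is the per-image magnitude noise SD). With Rician background
noise the probability of a pure-noise voxel passing k=5 is the
Rayleigh tail exp(−k²/2) ≈ 3.7×10⁻⁶.

### DCE pharmacokinetics

Extended Tofts model, with `Ktrans` (1/min) the plasma→EES volume
transfer constant, `ve` the extravascular-extracellular volume
fraction, `vp` the plasma volume fraction, and kep = Ktrans/ve the
reflux rate (never stored independently — it is a derived quantity
everywhere, including the cohort generator):

    Ct(t) = vp·Cp(t) + Ktrans · ∫₀ᵗ Cp(τ)·e^{−kep(t−τ)} dτ

Per-voxel chain:

1. **Two-point VFA T1.** The SPGR equation
   S = M0·sinα·(1−E1)/(1−E1·cosα), E1 = exp(−TR/T1), is linear in
   (S/sinα, S/tanα) space; the 5° pre-contrast volume and the mean of
   the pre-injection 15° dynamics give slope E1 and intercept exactly.
   A slope outside (0, 1) is non-physical and invalidates the voxel.
   Note that *equal* signals at the two angles are not automatically
   inconsistent: with 5°/15° and TR = 4.8 ms they are produced by
   T1 ≈ 418 ms (the Ernst-curve crossing) — the tests document this.
2. **Concentration.** The dynamic SPGR signal is inverted per time
   point reusing M0 from the VFA fit (the only self-consistent reading
   of a two-flip-angle protocol), giving R1(t); then
   Ct = (R1(t) − R1,baseline)/r1 with the baseline-mean forced to
   zero. Time points whose inversion fails are flagged; a voxel with
   > 20% failed points is excluded.
3. **Fit.** Bounded least squares for (Ktrans, ve, vp) with bounds
   [0, 5] /min × [10⁻³, 1] × [0, 0.5], deterministic start
   (0.3, 0.3, 0.05), no multi-start. Zero/flat curves and fits pinned
   at Ktrans = 0 are excluded as unphysiological.

**Convolution quadrature.** The exponential convolution is evaluated
as the one-pole recursion
I_k = e^{−kep·h}·I_{k−1} + (h/2)(Cp_k + e^{−kep·h}·Cp_{k−1})
(trapezoidal weights, run through `scipy.signal.lfilter`) on a 10×
upsampled uniform grid — the 9.2 s dynamic interval is coarse relative
to the bolus. The recursion is unconditionally overflow-free for any
kep ≥ 0 and matches the boxcar and mono-exponential closed forms to
≤ 0.1% (tested). Units: Ktrans/kep are stored in 1/min and converted
to 1/s internally at the boundary.

**ve unit.** ve and vp are treated as fractions in [0, 1]; published
group values of ~0.5–0.9 labelled "%" are plainly fractions, so the
percent label is treated as a typo.

## Synthetic data

### Phantoms

An ellipsoidal tumor ROI embedded in homogeneous muscle-like
background on a small voxel grid (default voxel 1.8×1.8×3.3 mm — the
230 mm FOV / 128 matrix in-plane, 3 mm slice + 0.3 mm gap).
Within-tumor heterogeneity is a log-normal perturbation of the
subject's mean parameters with CV = 10% (default), so voxel filters
and ROI averaging have realistic work to do. Hard physiological clips
keep every voxel valid (D* > D, ve + vp ≤ 1, ...).

### Acquisitions

- **DWI**: the forward model plus Rician noise — magnitude of the
  complex signal under Gaussian noise of SD `noise_sigma` per image.
  The stored series averages n_directions × n_averages (3 × 3 default)
  magnitude images, emulating the clinical protocol, so its effective
  noise is σ/3. Magnitude-domain averaging preserves the Rician
  background floor (mean σ√(π/2) where the true signal is zero).
- **DCE**: the Tofts concentration pushed through
  R1(t) = 1/T10 + r1·Ct(t) and the SPGR equation at 15°, plus a 5°
  pre-contrast volume; Gaussian noise (the enhanced dynamics are
  high-SNR, where Rician ≈ Gaussian). The DCE noise SD is scaled to
  match the *stored* DWI series' baseline SNR — the two series have
  very different absolute scales (SPGR baseline is only ~2–4% of M0),
  so a shared absolute σ would be meaningless.
- **AIF**: a population-average bolus (two Gaussians + sigmoid-gated
  exponential washout, standard literature constants), generated
  directly as plasma concentration on the dynamic grid and shifted so
  the bolus starts at the injection dynamic (8th of 65, Δt = 9.2 s
  ≈ 10 min/65). A measured patient AIF and its hematocrit correction
  are out of scope; a Hct parameter (0.42) exists only for the
  optional arterial-signal pathway. r1 defaults to 3.5 /(mM·s)
  (Gd-DOTA at 3 T).

### Cohorts

Two stage groups (defaults 29 low / 46 high). Per-subject ROI-mean
parameters are drawn from group-specific truncated-normal marginals
(defaults: the published NPC group means/SDs) through a Gaussian
copula with a single latent factor: loadings +√r on f, D*, Ktrans and
vp, −√r on ve, 0 on D, where r = 2·sin(π·ρ/6) converts the requested
pairwise Spearman ρ (`cross_correlation`, default 0.5) into the
Gaussian correlation. The quantile transform to the truncated normals
is monotone, so the Spearman correlation is preserved exactly; the
factor structure is positive-semidefinite by construction. ve loads
negatively because it moves opposite to the perfusion parameters
across stages. Pooling the two groups dilutes the within-group rank
correlation slightly (planted 0.5 → pooled ≈ 0.46).

Note the published kep row (0.885/0.748 ± SD) is *inconsistent* with
kep = Ktrans/ve applied to the published Ktrans and ve rows; the
generator samples (Ktrans, ve) and derives kep, so its kep spread is
wider than the printed row. The printed values are carried in the
default parameter set for reference only.

All randomness flows from a single seed through
`numpy.random.SeedSequence.spawn`; identical seeds give bit-identical
cohorts, maps and reports (checksummed in the pipeline manifest).

### What the generator does not emulate

Anatomically realistic anatomy, partial-volume effects, motion and
ghosting, B1/flip-angle miscalibration, water exchange, measured
patient AIFs, and inter-observer ROI variability. Passing tests
therefore demonstrate correctness of the estimators and statistics
under the stated generative model — not robustness to those real-data
confounds.

## Statistics layer

- **Stratification**: AJCC I–II → low, III–IV → high.
- **Student's t** (pooled variance; Welch behind a flag) on raw
  samples or on (mean, SD, n) summaries — the same closed form. A
  worked spot check: the published low/high diffusion summaries
  (0.803±0.188, n=29 vs 0.700±0.193, n=46) give t ≈ 2.27, p ≈ 0.026
  by this formula, although p < 0.001 is printed alongside them; the
  same holds for other rows (f gives p ≈ 0.27). The package computes,
  documents and asserts the closed-form value; it does not attempt to
  reconcile the discrepancy (different test, paired structure, or
  typo — undecidable from the published text).
- **ROC**: empirical curve over all midpoint thresholds; AUC by
  trapezoid (identical to the Mann–Whitney statistic, asserted to
  1e-12); optimal cut-off maximizing Youden's J (max-accuracy
  alternative via `criterion="accuracy"`), ties broken toward higher
  specificity; Clopper–Pearson CIs for sens/spec, log-method CIs for
  likelihood ratios. Direction is per parameter: low values of D, f,
  D*, Ktrans, kep, vp predict high stage; high ve does.
- **AUC comparison**: DeLong's paired test with midrank placements.
- **Stepwise logistic**: forward selection by likelihood-ratio test at
  p_enter = 0.05 with backward pruning at p_remove = 0.10, features
  z-standardized, exact-collinearity guard; (quasi-)separation is
  detected (non-convergence, |β| > 50 on standardized features, or
  SE > 10³) and falls back to an L2-penalized fit with a warning.
- **Spearman/Bonferroni**: midrank rho per named pair; m = the number
  of pairs actually tested (8 for the 2×4 IVIM-perfusion × DCE grid);
  p_adj = min(1, m·p). m is never hard-coded to reproduce any
  particular published corrected threshold.
- **Agreement**: Cohen's kappa after dichotomizing continuous
  measurements at the pooled median (the binning rule is an
  interpretation, exposed as a parameter; the published kappas on
  continuous parameters cannot be reproduced without a stated rule).
  Two-session repeat measurements are averaged per observer before
  cohort statistics.

## Problem sizes and tolerances

Chosen so the full suite runs comfortably on one CPU: noiseless
round-trip and SNR-50 recovery phantoms use 1000 voxels (noiseless
recovery is exact to ~1e-12; at SNR 50 the median relative errors are
≈2.5% for D, ≈3% for f, ≈9% for D*, ≈1% for Ktrans/ve/vp — D* is
consistently the most fragile parameter, as expected from its weak
signature at low b); calibration uses 5000 t-test replicates, 200
stepwise runs at n = 300 and 100 correlation cohorts; the end-to-end
staging check averages 6 replicate 75-subject cohorts on 8×8×4 grids
because single-cohort group-mean differences of the weaker parameters
(f, D*, vp) have sign-error probabilities up to ~25% under the
generative SDs — averaging replicates tests the same direction pattern
with Monte-Carlo error under control.

## Known limitations

- The segmented IVIM estimator inherits the usual small-b information
  limit: D* is poorly conditioned and its recovery error is always the
  largest (the tests assert this ordering rather than hide it).
- The two-point VFA T1 has no redundancy: with only two flip angles,
  noise propagates directly into T10/M0 and thence into Ct.
- vp is small (~0.07–0.09) and sits near its lower bound for weakly
  vascularized voxels; over-fitting concerns at low SNR are real and
  reflected in the wider recovery tolerance.
- The stepwise-selection protocol (thresholds, forward-LR form) is one
  of several defensible conventions and is fully configurable.
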