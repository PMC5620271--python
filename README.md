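# ivimdce

Quantitative MRI analysis of nasopharyngeal carcinoma (NPC) staging:
voxel-wise **intravoxel incoherent motion (IVIM)** diffusion fitting,
**extended-Tofts** dynamic contrast-enhanced (DCE) pharmacokinetic
fitting, and the cohort-level statistics that compare the resulting
parameters between low (AJCC I–II) and high (AJCC III–IV) stage groups.
Because no patient images are distributed, the package ships a
first-class synthetic-data layer — digital phantoms, noisy DWI/DCE
acquisitions and two-group cohorts with controllable cross-parameter
correlation — so the entire pipeline is testable end to end.

Intended for researchers in quantitative MRI and head-and-neck imaging
who want a reproducible, oracle-tested reference implementation of this
analysis chain.

## Models

**IVIM** separates molecular diffusion from capillary pseudodiffusion
in the multi-b-value signal decay:

    S(b)/S0 = (1 − f)·exp(−b·D) + f·exp(−b·(D + D*))

with D the true diffusion coefficient (mm²/s), f the perfusion
fraction and D* ≫ D the pseudodiffusion coefficient.  Fitting is
segmented: D from a log-linear fit over b > 200 s/mm² (where the
perfusion term is gone), then (f, D*, S0) by bounded nonlinear least
squares over all 13 b-values with D fixed.  Voxels whose b=0 signal is
not safely above the noise floor (< 5σ) are excluded.

**Extended Tofts** describes tissue contrast concentration against an
arterial input function Cp:

    Ct(t) = vp·Cp(t) + Ktrans · ∫₀ᵗ Cp(τ)·exp(−kep·(t−τ)) dτ,   kep = Ktrans/ve

Per voxel the chain is: two-point variable-flip-angle T1 mapping
(5° pre-contrast / 15° dynamics, spoiled-gradient-echo equation),
signal → concentration via the linear relaxivity relation
R1(t) = R1(0) + r1·Ct(t), then a bounded least-squares fit of
(Ktrans, ve, vp).  Non-enhancing ("unphysiological") voxels are
excluded.

**Statistics**: Shapiro–Wilk normality, pooled Student's t-tests,
empirical ROC curves with Youden-optimal cut-offs (sensitivity,
specificity, likelihood ratios with CIs), DeLong paired AUC
comparison, forward-stepwise logistic regression, and the 2×4 grid of
Spearman correlations between IVIM perfusion parameters (f, D*) and
DCE parameters (Ktrans, kep, ve, vp) with Bonferroni correction.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated 75-subject cohort (29 low / 46 high stage, reduced-resolution
8×8×4 grids, cross-parameter Spearman correlation 0.5):

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_fit_parameter_maps.py --seed 0
python analysis/03_cohort_statistics.py
python analysis/04_recovery_benchmark.py --seed 0
```

Script 03 prints (seed 0):

```
n = 29 low / 46 high stage
mean_D        low 0.0008378 vs high 0.0007033  t=+2.92 p=0.00461  AUC=0.684  cutoff=0.000697 (sens 50%, spec 86%)
mean_Ktrans   low 0.6651 vs high 0.5083  t=+5.39 p=8.25e-07  AUC=0.845  cutoff=0.6004 (sens 76%, spec 90%)
mean_vp       low 0.124 vs high 0.07863  t=+3.64 p=0.000508  AUC=0.722  cutoff=0.09377 (sens 65%, spec 72%)
...
stepwise selected: ['mean_Ktrans', 'mean_D', 'mean_f']
  rho(mean_Dstar, mean_Ktrans) = +0.543* (Bonferroni p = 3.88e-06)
  rho(mean_f, mean_ve) = -0.508* (Bonferroni p = 2.64e-05)
```

Reading: every parameter except ve is lower in the high-stage group
(ve is higher), Ktrans is the strongest single discriminator by AUC
and is selected first by the stepwise model, and the IVIM perfusion
parameters correlate positively with Ktrans/kep/vp and negatively with
ve — the qualitative pattern this analysis is designed to expose.
Exact numbers vary with the cohort seed, as they would across patient
samples.

The same pipeline is available as a CLI
(`ivimdce simulate-cohort | fit-ivim | fit-dce | roi-extract |
cohort-stats | run-all`) for file-based workflows on NIfTI inputs.

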