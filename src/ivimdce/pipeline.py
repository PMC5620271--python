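"""End-to-end pipeline: simulation → voxel fits → ROI table → statistics.

Every artifact is regenerable from (config, seed) alone; a manifest
records per-stage SHA-256 checksums so reruns can be verified
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aif import population_aif
from .cohort import simulate_cohort
from .config import PipelineConfig
from .dce import fit_dce_map
from .errors import FitError
from .ivim import fit_ivim_map
from .roi import MIN_TUMOR_VOLUME, build_subject_record, records_to_frame, tumor_volume
from .stats import (
    HIGHER_IN_HIGH_STAGE,
    LOWER_IN_HIGH_STAGE,
    compare_auc,
    roc_analysis,
    shapiro_wilk,
    spearman_with_bonferroni,
    stepwise_logistic,
    stratify_frame,
    t_test_two_sample,
)

log = logging.getLogger("ivimdce")

PARAM_COLUMNS = ("mean_D", "mean_f", "mean_Dstar", "mean_Ktrans",
                 "mean_kep", "mean_ve", "mean_vp")

#: IVIM-perfusion × DCE correlation grid (2 × 4 = 8 pairs).
CORRELATION_PAIRS = [
    (ivim_p, dce_p)
    for ivim_p in ("mean_f", "mean_Dstar")
    for dce_p in ("mean_Ktrans", "mean_kep", "mean_ve", "mean_vp")
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fit_cohort(subjects, fit_options, noise_sigma: float) -> pd.DataFrame:
    """Run both voxel-wise fits for every subject and build the cohort
    table; subjects below the tumor-volume floor are excluded."""
    records = []
    n_excluded_volume = 0
    for subj in subjects:
        vol = tumor_volume(subj.truth.roi_mask, subj.truth.voxel_size)
        if vol < MIN_TUMOR_VOLUME:
            n_excluded_volume += 1
            log.info("excluding %s: tumor volume %.2f mm³ below %.2f",
                     subj.subject_id, vol, MIN_TUMOR_VOLUME)
            continue
        try:
            imaps = fit_ivim_map(
                subj.dwi.data, subj.dwi.scheme, subj.truth.roi_mask,
                noise_sigma=noise_sigma if noise_sigma > 0 else None,
                snr_k=fit_options.snr_k,
                b_threshold=fit_options.b_threshold,
                refine_D=fit_options.refine_D,
            )
            aif = population_aif(subj.dce.scheme)
            tmaps = fit_dce_map(
                subj.dce.data, subj.dce.pre_volume, subj.truth.roi_mask,
                aif, subj.dce.scheme,
            )
            rec = build_subject_record(
                subj.subject_id, subj.stage_group, subj.ajcc_stage,
                subj.truth.roi_mask, subj.truth.voxel_size, imaps, tmaps,
            )
        except FitError as exc:
            raise FitError(f"subject {subj.subject_id}, fitting stage: {exc}") from exc
        n_roi = int(subj.truth.roi_mask.sum())
        log.info("%s: %d ROI voxels, %d IVIM-valid, %d DCE-valid",
                 subj.subject_id, n_roi, int(imaps.valid_mask.sum()),
                 int(tmaps.valid_mask.sum()))
        records.append(rec)
    if n_excluded_volume:
        log.info("excluded %d subjects below the volume floor", n_excluded_volume)
    return records_to_frame(records)


def cohort_statistics(table: pd.DataFrame, alpha: float = 0.05,
                      criterion: str = "youden") -> dict:
    """The full staging statistics block over a cohort table."""
    report: dict = {"n_low": int((table["stage_group"] == "low").sum()),
                    "n_high": int((table["stage_group"] == "high").sum()),
                    "parameters": {}}
    y = (table["stage_group"] == "high").to_numpy()

    for col in PARAM_COLUMNS:
        low, high = stratify_frame(table, col)
        direction = "lower" if col in LOWER_IN_HIGH_STAGE else "higher"
        _, p_sw_low = shapiro_wilk(low)
        _, p_sw_high = shapiro_wilk(high)
        t, p_t = t_test_two_sample(low, high)
        roc = roc_analysis(table[col].to_numpy(float), y, direction=direction,
                           criterion=criterion)
        report["parameters"][col] = {
            "mean_low": float(low.mean()), "sd_low": float(low.std(ddof=1)),
            "mean_high": float(high.mean()), "sd_high": float(high.std(ddof=1)),
            "shapiro_p": [p_sw_low, p_sw_high],
            "t": t, "p_t": p_t,
            "direction": direction,
            "auc": roc.auc,
            "optimal_cutoff": roc.optimal_cutoff,
            "sensitivity": roc.sens, "specificity": roc.spec,
            "lr_pos": roc.lr_pos, "lr_neg": roc.lr_neg,
        }

    # paired AUC comparisons of the strongest DCE marker vs IVIM perfusion
    report["auc_comparison"] = {}
    for a, b in (("mean_Ktrans", "mean_f"), ("mean_Ktrans", "mean_Dstar")):
        sa = table[a].to_numpy(float) * (-1 if a in LOWER_IN_HIGH_STAGE else 1)
        sb = table[b].to_numpy(float) * (-1 if b in LOWER_IN_HIGH_STAGE else 1)
        diff, p = compare_auc(sa, sb, y)
        report["auc_comparison"][f"{a}_vs_{b}"] = {"auc_diff": diff, "p": p}

    # stepwise multiple logistic regression over all seven parameters
    # (needs more subjects than candidates; tiny smoke cohorts skip it)
    X = table[list(PARAM_COLUMNS)].to_numpy(float)
    if len(table) > len(PARAM_COLUMNS):
        sw = stepwise_logistic(X, y, feature_names=list(PARAM_COLUMNS))
        report["stepwise"] = {
            "selected": sw.selected,
            "selection_order": sw.selection_order,
            "coefficients": sw.coefficients,
            "wald_p": sw.wald_p,
            "deviance": sw.deviance,
            "penalized": sw.penalized,
        }
    else:
        report["stepwise"] = {
            "skipped": "fewer subjects than candidate predictors"}

    # Spearman correlations, IVIM perfusion × DCE grid, Bonferroni m=8
    pairs = [(a, b, table[a].to_numpy(float), table[b].to_numpy(float))
             for a, b in CORRELATION_PAIRS]
    report["correlations"] = [
        {"pair": list(r.pair), "rho": r.rho, "p_raw": r.p_raw,
         "p_adjusted": r.p_adjusted, "m": r.m, "significant": r.significant}
        for r in spearman_with_bonferroni(pairs, alpha=alpha)
    ]
    return report


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate the cohort, fit every subject, and compute the report.

    Writes truth.csv, cohort.csv, aif.csv, report.json and
    manifest.json under the output directory and returns the report.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = replace(config.cohort, seed=config.seed)

    log.info("simulating cohort: %d low + %d high subjects",
             spec.n_low, spec.n_high)
    aif = population_aif(config.dce_scheme)
    subjects, truth_table = simulate_cohort(
        spec, config.dwi_scheme, config.dce_scheme, aif)
    truth_table.to_csv(out / "truth.csv", index=False)

    table = fit_cohort(subjects, config.fit, spec.noise_sigma)
    table.to_csv(out / "cohort.csv", index=False)

    from .io import save_aif
    save_aif(aif, out / "aif.csv")

    report = cohort_statistics(table, alpha=config.fit.alpha,
                               criterion=config.fit.cutoff_criterion)
    report["seed"] = config.seed
    report["version"] = __version__
    (out / "report.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(_config_dict(config))),
        "checksums": {
            name: _sha256(out / name)
            for name in ("truth.csv", "cohort.csv", "aif.csv", "report.json")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _config_dict(config: PipelineConfig) -> dict:
    from .config import _listify

    return _listify(asdict(config))
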