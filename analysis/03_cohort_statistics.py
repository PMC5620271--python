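#!/usr/bin/env python
"""Staging statistics over the fitted cohort table.

Per parameter: two-group Student's t-test, ROC with the Youden-optimal
cut-off, sensitivity/specificity and likelihood ratios; plus the
stepwise logistic model, the DeLong AUC comparisons and the 2x4
IVIM-perfusion x DCE Spearman grid with Bonferroni correction.
Reads results/cohort/cohort.csv (run 02 first); writes the JSON report
and the correlation grid CSV next to it.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ivimdce.pipeline import cohort_statistics

parser = argparse.ArgumentParser()
parser.add_argument("--table", type=Path, default=Path("results/cohort/cohort.csv"))
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

table = pd.read_csv(args.table)
report = cohort_statistics(table)

args.out.mkdir(parents=True, exist_ok=True)
(args.out / "stats_report.json").write_text(json.dumps(report, indent=2))
pd.DataFrame([
    {"pair": "-".join(c["pair"]), "rho": c["rho"], "p_raw": c["p_raw"],
     "p_adjusted": c["p_adjusted"], "significant": c["significant"]}
    for c in report["correlations"]
]).to_csv(args.out / "correlations.csv", index=False)

print(f"n = {report['n_low']} low / {report['n_high']} high stage")
for name, d in report["parameters"].items():
    print(f"{name:13s} low {d['mean_low']:.4g} vs high {d['mean_high']:.4g}  "
          f"t={d['t']:+.2f} p={d['p_t']:.3g}  AUC={d['auc']:.3f}  "
          f"cutoff={d['optimal_cutoff']:.4g} "
          f"(sens {100 * d['sensitivity']:.0f}%, spec {100 * d['specificity']:.0f}%)")
print("stepwise selected:", report["stepwise"].get("selected"))
for c in report["correlations"]:
    star = "*" if c["significant"] else " "
    print(f"  rho({c['pair'][0]}, {c['pair'][1]}) = {c['rho']:+.3f}{star} "
          f"(Bonferroni p = {c['p_adjusted']:.3g})")
print(f"wrote {args.out / 'stats_report.json'}")
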