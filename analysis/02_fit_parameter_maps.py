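#!/usr/bin/env python
"""Fit IVIM and extended-Tofts maps for every simulated subject.

Re-simulates the cohort deterministically from the seed (no
intermediate storage needed), runs the segmented IVIM fit and the full
DCE chain per voxel, and writes the per-subject ROI-mean cohort table
to results/cohort/cohort.csv.
"""

import argparse
import time
from pathlib import Path

from ivimdce import CohortSpec, DceScheme, DwiScheme, simulate_cohort
from ivimdce.config import FitOptions
from ivimdce.pipeline import fit_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

spec = CohortSpec(n_low=29, n_high=46, shape=(8, 8, 4),
                  cross_correlation=0.5, seed=args.seed)
subjects, _ = simulate_cohort(spec, DwiScheme(), DceScheme())

t0 = time.time()
table = fit_cohort(subjects, FitOptions(), spec.noise_sigma)
args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "cohort.csv", index=False)

print(f"fitted {len(table)} subjects in {time.time() - t0:.1f} s")
print("fitted ROI-mean group averages:")
cols = ["mean_D", "mean_f", "mean_Dstar", "mean_Ktrans", "mean_kep",
        "mean_ve", "mean_vp"]
print(table.groupby("stage_group")[cols].mean().round(4).to_string())
print(f"wrote {args.out / 'cohort.csv'}")
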