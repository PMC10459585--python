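#!/usr/bin/env python
"""Predict release curves and score the predictions with RMSEP.

Two procedures per the study design: (a) transfer of the fitted Higuchi
constant D_k between implants of the same strand width (pore size 0.4 mm
excluded), scaled by the target's measured eluting area; (b) √t
extrapolation of each implant's first 15 days over the remaining 75
days, evaluated up to 60 % release.  RMSEP < 5 % of dose counts as an
acceptable prediction.
"""

import itertools
from pathlib import Path

import pandas as pd

import gridrelease as gr
from gridrelease.accounting import read_profile_csv

ROOT = Path(__file__).resolve().parent.parent / "results"
AREAS = {rec.name: rec.area_true_cm2 for rec in gr.STUDY_IMPLANTS}

profiles = {}
for path in sorted((ROOT / "profiles").glob("*.csv")):
    p = read_profile_csv(path)
    if p.unit_id in AREAS:
        profiles[p.unit_id] = p

rows = []
by_width = {}
for rec in gr.STUDY_IMPLANTS:
    if rec.pore_size != 0.4 and rec.name in profiles:
        by_width.setdefault(rec.strand_width, []).append(rec.name)
for width, names in sorted(by_width.items()):
    for donor, target in itertools.permutations(names, 2):
        fit = gr.higuchi_fit(profiles[donor], AREAS[donor])
        res = gr.dk_transfer(fit, profiles[target], AREAS[target])
        rows.append({"method": "dk_transfer", "source": donor, "target": target,
                     "rmsep_pct": round(res.rmsep_pct, 2),
                     "acceptable": gr.assess(res.rmsep_pct)})

for unit, profile in profiles.items():
    res = gr.predict_from_early(profile, training_horizon_d=15.0, horizon_d=90.0)
    rows.append({"method": "early_extrapolation", "source": "", "target": unit,
                 "rmsep_pct": round(res.rmsep_pct, 2),
                 "r2": round(res.regression_r2, 4),
                 "acceptable": gr.assess(res.rmsep_pct)})

df = pd.DataFrame(rows)
df.to_csv(ROOT / "predictions.csv", index=False)
print(df.to_string(index=False))
early = df[df["method"] == "early_extrapolation"]
transfer = df[df["method"] == "dk_transfer"]
print(f"\nearly extrapolation: {early['acceptable'].mean():.0%} of implants "
      f"below the 5 % bound; worst RMSEP {early['rmsep_pct'].max():.2f} %")
print(f"D_k transfer: RMSEP {transfer['rmsep_pct'].min():.2f}–"
      f"{transfer['rmsep_pct'].max():.2f} %, "
      f"{transfer['acceptable'].mean():.0%} acceptable — on these synthetic "
      "curves same-width implants do not share kinetics (exponent and "
      "per-area release differ by design), so cross-geometry transfer "
      "carries a larger error than the early-data route.")
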