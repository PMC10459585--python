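#!/usr/bin/env python
"""Fit release-kinetics models to the reconstructed profiles.

Fits the power law (diffusional exponent + mechanism class), Higuchi
(lumped constant D_k per measured eluting area), Peppas–Sahlin and
Weibull models over the 5–60 % release window and writes one row per
unit × model to results/kinetics_fits.csv.
"""

from pathlib import Path

import pandas as pd

import gridrelease as gr
from gridrelease.accounting import read_profile_csv

ROOT = Path(__file__).resolve().parent.parent / "results"
AREAS = {rec.name: rec.area_true_cm2 for rec in gr.STUDY_IMPLANTS}
AREAS["filament"] = 4.12  # theoretical filament area, cm²

rows = []
for path in sorted((ROOT / "profiles").glob("*.csv")):
    profile = read_profile_csv(path)
    unit = profile.unit_id
    if unit == "suspension":
        continue  # dissolves in minutes; matrix models do not apply
    kp = gr.kp_fit(profile)
    rows.append({"unit_id": unit, "model": "korsmeyer_peppas",
                 **{k: round(v, 4) for k, v in kp.params.items()},
                 "r2": round(kp.r_squared, 4),
                 "mechanism": gr.classify_mechanism(kp.params["n"]).label})
    hig = gr.higuchi_fit(profile, AREAS[unit])
    rows.append({"unit_id": unit, "model": "higuchi",
                 "dk": round(hig.params["dk"], 4),
                 "intercept": round(hig.params["intercept"], 4),
                 "r2": round(hig.r_squared, 4)})
    for model in ("peppas_sahlin", "weibull"):
        fit = gr.nonlinear_fit(profile, model)
        rows.append({"unit_id": unit, "model": model,
                     **{k: round(v, 5) for k, v in fit.params.items()},
                     "r2": round(fit.r_squared, 4), "converged": fit.converged})

df = pd.DataFrame(rows)
df.to_csv(ROOT / "kinetics_fits.csv", index=False)
print(df.to_string(index=False))
print("\nOn these burst + power-law curves the windowed log-log exponent "
      "sits below the underlying matrix exponent (the saturating burst "
      "flattens the slope); the Higuchi fits stay nearly linear, which is "
      "what the square-root prediction procedures rely on.")
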