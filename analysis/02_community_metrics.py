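#!/usr/bin/env python
"""Community metrics per subplot and their N-treatment tests.

Reads the study CSVs from results/study/, computes ANPP, Shannon H',
light-asymmetry slope and herbivory intensity for every subplot, tests each
against N treatment (Bonferroni alpha = 0.05/4), and reports the
ANPP-vs-light-asymmetry collinearity diagnostic that decides which
covariates continue downstream.

    python analysis/02_community_metrics.py [--study results/study]
"""

import argparse
import json
from pathlib import Path

from foxsel.community import (
    anpp_light_asymmetry_correlation,
    metrics_table,
    test_all_metrics,
)
from foxsel.core_data import StudyDesign, read_community, read_individuals, read_par

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--out", type=Path, default=Path("results/community"))
args = ap.parse_args()

individuals, _ = read_individuals(args.study / "individuals.csv")
community, _ = read_community(args.study / "community.csv")
par, _ = read_par(args.study / "par.csv")
design = StudyDesign.from_records(individuals)

metrics = metrics_table(individuals, community, par, design)
tests = test_all_metrics(metrics, individuals, design)
r, p = anpp_light_asymmetry_correlation(metrics)

args.out.mkdir(parents=True, exist_ok=True)
metrics.to_csv(args.out / "community_metrics.csv", index=False, float_format="%.6g")
(args.out / "treatment_tests.json").write_text(
    json.dumps(
        {m: t.as_dict() for m, t in tests.items()}
        | {"anpp_light_asymmetry_r": r, "anpp_light_asymmetry_p": p},
        indent=2, sort_keys=True,
    )
    + "\n"
)

print("per-treatment means:")
print(metrics.groupby("treatment")[
    ["anpp", "shannon_h", "light_asymmetry_beta", "herbivory_intensity"]
].mean().round(3).to_string())
for m, t in tests.items():
    mark = "*" if t.significant else " "
    print(f"  {m:<22s} chi2={t.statistic:7.2f}  p={t.p_value:.4f} {mark} ({t.method})")
print(f"ANPP ~ light asymmetry: r={r:.2f} (p={p:.3g}); when strongly collinear "
      "only light asymmetry is carried into covariate models")
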