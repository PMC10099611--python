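#!/usr/bin/env python
"""Blocked PERMANOVAs: do community metrics shape multivariate selection?

Uses per-subplot selection-coefficient vectors (and |coefficients| vs I,
and the six pairwise phenotypic correlations vs N treatment) as responses
in PERMANOVAs with plot-restricted permutations — with 6 plots of 2
subplots the full 2^6 = 64 relabellings are enumerated, so the smallest
attainable p is 1/64 ~ 0.016.

    python analysis/05_permanova_correlates.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from foxsel.pipeline import RunConfig, run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--study", type=Path, default=Path("results/study"))
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/permanova"))
args = ap.parse_args()

cfg = RunConfig(
    seed=args.seed, B=100, bootstrap_method="pooled", n_perm="exhaustive",
    individuals_path=str(args.study / "individuals.csv"),
    community_path=str(args.study / "community.csv"),
    par_path=str(args.study / "par.csv"),
)
bundle = run_pipeline(cfg, stages={"selection", "opportunity"})
if bundle.errors:
    raise SystemExit(f"stage failures: {bundle.errors}")

reports = {
    "correlations_vs_treatment": bundle.reports["correlation_permanova"],
    **bundle.reports.get("selection_vs_metric_permanova", {}),
    "abs_differentials_vs_I": bundle.reports.get("abs_differentials_vs_I_permanova"),
    "abs_gradients_vs_I": bundle.reports.get("abs_gradients_vs_I_permanova"),
}
args.out.mkdir(parents=True, exist_ok=True)
(args.out / "permanova.json").write_text(
    json.dumps(reports, indent=2, sort_keys=True) + "\n"
)

print("blocked-permutation PERMANOVAs (exhaustive 64-set):")
for name, rep in reports.items():
    if rep is None or "pseudo_F" not in rep:
        print(f"  {name:<42s} -")
        continue
    print(f"  {name:<42s} F={rep['pseudo_F']:6.2f}  p={rep['p_value']:.4f} "
          f"(df {rep['df_num']},{rep['df_den']})")
print(f"wrote {args.out}/permanova.json")
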