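"""End-to-end orchestration: one config in, one result bundle out.

The bundle mirrors the study's result surfaces: per-subplot community
metrics with treatment tests, trait-mean and hurdle fitness tests, a
Table-1-style selection table (differentials and gradients with clustered
bootstrap CIs and addition-ambient difference CIs), per-subplot coefficient
tables, Table-2-style correlation matrices with the blocked correlation
PERMANOVA, opportunity-for-selection records with their treatment test and
community-metric associations, coefficient-vs-metric and |coefficient|-vs-I
PERMANOVAs, and a QC report.

Every output is a pure function of (inputs, config, seed); tables carry the
config hash and seed so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import core_data as cd
from . import opportunity as opp
from . import resampling as rs
from . import selection as sel
from . import synthetic as syn

STAGES = ("validate", "metrics", "traits", "selection", "opportunity", "qc")


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable)."""

    seed: int = 0
    B: int = 1000  # bootstrap replicates per treatment
    n_perm: object = "auto"  # "auto"/"exhaustive" or an int
    estimate_method: str = "mixed"  # point-estimate backend
    bootstrap_method: str = "mixed"  # backend re-run inside each replicate
    per_subplot: str = "conditional"  # or "subplot_ols"
    ci_level: float = 0.95
    min_subplot_n: int = 1
    log_base: str = "ln"  # PAR regression log base, recorded in metadata
    synthetic: dict | None = None  # SyntheticParams overrides; None = read files
    individuals_path: str | None = None
    community_path: str | None = None
    par_path: str | None = None
    column_map: dict | None = None

    def __post_init__(self):
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if self.seed is None:
            raise ValueError("a seed is required: stochastic stages run")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    reports: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def meta(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "B": self.config.B,
            "log_base": self.config.log_base,
            "stages_failed": sorted(self.errors),
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = self.meta
        for name, df in sorted(self.tables.items()):
            d = df.copy()
            d.insert(0, "config_hash", meta["config_hash"])
            d.insert(1, "seed", meta["seed"])
            d.to_csv(out / f"{name}.csv", index=False, float_format="%.12g")
        for name, rep in sorted(self.reports.items()):
            payload = {"config_hash": meta["config_hash"], "seed": meta["seed"], **rep}
            (out / f"{name}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n"
            )
        (out / "meta.json").write_text(
            json.dumps({**meta, "errors": self.errors}, indent=2, sort_keys=True) + "\n"
        )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_inputs(config: RunConfig):
    """Load the three data tables per config: synthetic or from files."""
    if config.synthetic is not None:
        params = syn.SyntheticParams(**config.synthetic)
        study = syn.generate_study(params, seed=config.seed)
        return study.individuals, study.community, study.par, study.design, study.ground_truth
    if not (config.individuals_path and config.community_path and config.par_path):
        raise ValueError("either synthetic params or all three input paths are required")
    individuals, _ = cd.read_individuals(
        config.individuals_path, column_map=config.column_map
    )
    community, _ = cd.read_community(config.community_path)
    par, _ = cd.read_par(config.par_path)
    design = cd.StudyDesign.from_records(individuals)
    return individuals, community, par, design, None


def _selection_stage(bundle, individuals, design, config: RunConfig):
    sdf = sel.standardized_dataset(individuals)
    traits = cd.TRAITS

    # point estimates
    diff_coeffs, diff_per_sub = sel.estimate_differentials(
        sdf, method=config.estimate_method, per_subplot=config.per_subplot
    )
    grad_coeffs, grad_per_sub = sel.estimate_gradients(
        sdf, method=config.estimate_method, per_subplot=config.per_subplot
    )
    nonlinear = sel.estimate_nonlinear(sdf, method=config.estimate_method)

    # clustered bootstrap CIs per treatment, shared resamples per treatment
    fitness_raw, _ = cd.apply_fitness_exclusions(individuals)
    fitness_raw = fitness_raw.dropna(subset=["fruit_count"])
    ensembles: dict[tuple[str, str], rs.BootstrapEnsemble] = {}
    for t_index, trt in enumerate(cd.TREATMENTS):
        d_trt = fitness_raw[fitness_raw["treatment"] == trt]
        seed_trt = 2 * config.seed + 1 + t_index
        for kind, joint in (("differential", False), ("gradient", True)):
            if config.bootstrap_method == "pooled":
                ensembles[(kind, trt)] = sel.pooled_cases_bootstrap(
                    d_trt, traits, joint=joint, B=config.B, seed=seed_trt, scope=trt
                )
            else:
                estimator = (
                    _gradient_estimator(traits, config.bootstrap_method)
                    if joint
                    else _differential_estimator(traits, config.bootstrap_method)
                )
                ensembles[(kind, trt)] = rs.cases_bootstrap(
                    d_trt, estimator, B=config.B, seed=seed_trt, scope=trt
                )

    all_coeffs = diff_coeffs + grad_coeffs
    for c in all_coeffs:
        ens = ensembles[(c.kind, c.scope)]
        j = ens.coefficient_ids.index(c.trait)
        lo, hi = rs.percentile_ci(ens, config.ci_level)
        c.ci_low, c.ci_high = float(lo[j]), float(hi[j])

    table1 = sel.coefficients_frame(all_coeffs + nonlinear)
    bundle.tables["selection_coefficients"] = table1
    bundle.tables["selection_per_subplot_differentials"] = diff_per_sub
    bundle.tables["selection_per_subplot_gradients"] = grad_per_sub

    diffs = []
    for kind in ("differential", "gradient"):
        dd = rs.treatment_difference_ci(
            ensembles[(kind, "ambient")],
            ensembles[(kind, "addition")],
            level=config.ci_level,
        )
        dd.insert(0, "kind", kind)
        point = {
            c.trait: c.estimate for c in all_coeffs if c.kind == kind and c.scope == "addition"
        }
        point_amb = {
            c.trait: c.estimate for c in all_coeffs if c.kind == kind and c.scope == "ambient"
        }
        dd["difference_point"] = [
            point[t] - point_amb[t] for t in dd["coefficient"]
        ]
        diffs.append(dd)
    bundle.tables["selection_treatment_differences"] = pd.concat(diffs, ignore_index=True)

    bundle.reports["bootstrap_summary"] = {
        f"{kind}_{trt}": {
            "B": e.B, "failures": e.failures, "seed": e.seed, "valid": e.valid
        }
        for (kind, trt), e in ensembles.items()
    }
    return sdf, diff_per_sub, grad_per_sub


def _differential_estimator(traits, method):
    def est(df: pd.DataFrame) -> pd.Series:
        s = sel.relativize_fitness(sel.standardize_traits(df, traits))
        out = {}
        for t in traits:
            if method == "pooled":
                slopes, _ = sel._pooled_ols(s, [f"z_{t}"])
                out[t] = slopes[0]
            else:
                fixed, _, _ = sel._mixed_slopes(s, [f"z_{t}"])
                out[t] = fixed[f"z_{t}"]
        return pd.Series(out)

    return est


def _gradient_estimator(traits, method):
    zcols = [f"z_{t}" for t in traits]

    def est(df: pd.DataFrame) -> pd.Series:
        s = sel.relativize_fitness(sel.standardize_traits(df, traits))
        if method == "pooled":
            slopes, _ = sel._pooled_ols(s, zcols)
            return pd.Series(dict(zip(traits, slopes)))
        fixed, _, _ = sel._mixed_slopes(s, zcols)
        return pd.Series({t: fixed[f"z_{t}"] for t in traits})

    return est


def run_pipeline(config: RunConfig, stages: set[str] | None = None) -> ResultBundle:
    """Run the analysis end to end (or a subset of stages).

    A failing stage is recorded in ``bundle.errors`` and only its dependents
    are skipped.
    """
    wanted = set(STAGES) if stages is None else set(stages)
    bundle = ResultBundle(config)
    individuals, community, par, design, truth = load_inputs(config)
    if truth is not None:
        bundle.reports["ground_truth"] = truth

    if "validate" in wanted:
        try:
            summary = cd.validate_design(individuals, design, min_n=config.min_subplot_n)
            bundle.tables["design_summary"] = summary.per_subplot
            bundle.reports["design_report"] = {
                "total": summary.total,
                "per_treatment": summary.per_treatment,
                "low_n_subplots": summary.low_n_subplots,
            }
        except cd.DataError as exc:
            bundle.errors["validate"] = str(exc)

    metrics = None
    if "metrics" in wanted or "opportunity" in wanted or "selection" in wanted:
        try:
            metrics = comm.metrics_table(individuals, community, par, design)
        except cd.DataError as exc:
            bundle.errors["metrics"] = str(exc)
    if "metrics" in wanted and metrics is not None:
        bundle.tables["community_metrics"] = metrics
        tests = comm.test_all_metrics(metrics, individuals, design)
        bundle.reports["community_metric_tests"] = {
            m: t.as_dict() for m, t in tests.items()
        }
        r, p = comm.anpp_light_asymmetry_correlation(metrics)
        bundle.reports["anpp_light_asymmetry"] = {
            "r": r, "p": p,
            "note": "when strongly collinear only light asymmetry enters covariate models",
        }

    if "traits" in wanted:
        try:
            trait_tests = {
                t: sel.test_treatment_effect_on_trait(individuals, t)
                for t in cd.TRAITS
            }
            bundle.reports["trait_mean_tests"] = {
                t: v.as_dict() for t, v in trait_tests.items()
            }
            hurdle = sel.fit_hurdle_fitness(individuals)
            bundle.reports["hurdle_fitness"] = {
                "survival": None if hurdle.survival is None else hurdle.survival.as_dict(),
                "fecundity": None if hurdle.fecundity is None else hurdle.fecundity.as_dict(),
                "notes": hurdle.notes,
            }
        except (cd.DataError, Exception) as exc:  # stage isolation
            bundle.errors["traits"] = str(exc)

    diff_per_sub = grad_per_sub = None
    if "selection" in wanted:
        try:
            sdf, diff_per_sub, grad_per_sub = _selection_stage(
                bundle, individuals, design, config
            )
            # phenotypic correlations (Table 2 analogue) + blocked PERMANOVA
            _, trait_only = cd.apply_fitness_exclusions(individuals)
            corrs = [
                sel.phenotypic_correlations(
                    trait_only[trait_only["treatment"] == trt], scope=trt
                ).tidy()
                for trt in cd.TREATMENTS
            ]
            bundle.tables["phenotypic_correlations"] = pd.concat(corrs, ignore_index=True)
            vecs = sel.subplot_correlation_vectors(trait_only)
            sub_trt = design.subplot_treatment()
            sub_plot = design.subplot_plot()
            pr = rs.permanova(
                vecs.to_numpy(),
                np.array([sub_trt[s] for s in vecs.index]),
                np.array([sub_plot[s] for s in vecs.index]),
                n_perm=config.n_perm,
                seed=config.seed,
            )
            bundle.reports["correlation_permanova"] = pr.as_dict()

            # coefficient vectors vs community metrics (3 + 3 PERMANOVAs)
            if metrics is not None:
                alpha3 = rs.bonferroni_threshold(0.05, 3)
                res = {}
                for kind, per in (
                    ("differentials", diff_per_sub),
                    ("gradients", grad_per_sub),
                ):
                    merged = per.merge(
                        metrics[["subplot_id", "plot_id", "light_asymmetry_beta",
                                 "shannon_h", "herbivory_intensity"]],
                        on="subplot_id",
                    ).sort_values("subplot_id")
                    for metric in ("light_asymmetry_beta", "shannon_h", "herbivory_intensity"):
                        r = rs.permanova(
                            merged[list(cd.TRAITS)].to_numpy(float),
                            merged[metric].to_numpy(float),
                            merged["plot_id"].to_numpy(),
                            n_perm=config.n_perm,
                            seed=config.seed,
                        )
                        res[f"{kind}_vs_{metric}"] = {
                            **r.as_dict(), "adjusted_alpha": alpha3
                        }
                bundle.reports["selection_vs_metric_permanova"] = res
        except (cd.DataError, rs.ResamplingError) as exc:
            bundle.errors["selection"] = str(exc)

    if "opportunity" in wanted:
        try:
            opp_table = opp.opportunity_table(individuals, design)
            bundle.tables["opportunity"] = opp_table
            bundle.reports["opportunity_treatment_test"] = opp.test_treatment_effect_on_I(
                opp_table
            ).as_dict()
            if metrics is not None:
                assoc = {}
                for metric in ("light_asymmetry_beta", "shannon_h", "herbivory_intensity"):
                    assoc[metric] = opp.associate_I_with_metric(
                        opp_table, metrics, metric
                    ).as_dict()
                bundle.reports["opportunity_metric_associations"] = assoc
            if diff_per_sub is not None:
                for kind, per in (
                    ("differentials", diff_per_sub),
                    ("gradients", grad_per_sub),
                ):
                    try:
                        r = opp.selection_strength_vs_I(
                            per, opp_table, traits=cd.TRAITS,
                            n_perm=config.n_perm, seed=config.seed,
                        )
                        bundle.reports[f"abs_{kind}_vs_I_permanova"] = r.as_dict()
                    except (rs.ResamplingError, cd.DataError) as exc:
                        bundle.reports[f"abs_{kind}_vs_I_permanova"] = {
                            "error": f"no variation: {exc}"
                        }
        except cd.DataError as exc:
            bundle.errors["opportunity"] = str(exc)

    if "qc" in wanted:
        try:
            r, p, n = cd.panicle_qc(individuals)
            bundle.reports["panicle_qc"] = {"r": r, "p": p, "n": n}
        except cd.DataError as exc:
            bundle.reports["panicle_qc"] = {"error": str(exc)}
    return bundle
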