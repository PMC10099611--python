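"""Synthetic study generator emulating the N-addition field design.

Generates complete studies — individual trait/fitness records, subplot
species-biomass tables, and PAR-by-height profiles — with the statistical
structure the analysis assumes: six plots each split into an ambient and a
fertilized subplot, ~100 focal individuals per subplot, correlated traits
whose means and correlation matrices differ by treatment, hurdle fitness
(logit survival around 84%, overdispersed negative-binomial fecundity), and
treatment effects on productivity, diversity, light asymmetry, and
herbivory.

Selection enters the fitness model through coefficients on the
**within-subplot standardized** traits, so generating values are directly
comparable to estimated differentials and gradients.  Two fitness surfaces
are available:

* ``"hurdle"`` (default) — survival Bernoulli on a logit scale linear in z,
  positive fecundity zero-truncated negative binomial with log mean linear
  in z: the data-generating model of the field study;
* ``"lognormal"`` — W = exp(beta . z) x multiplicative noise.  Under
  multivariate-normal traits Stein's lemma makes the population Lande–Arnold
  gradient *exactly* beta and the differential vector *exactly* R beta, so
  this surface is the oracle for estimator checks.

Plot and subplot heterogeneity enters as additive shifts on trait means and
on log-fecundity intercepts, giving the clustered bootstrap and the mixed
models genuine hierarchical structure to work against.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import SEEDLING_CLASSES, TRAITS, TREATMENTS, StudyDesign

#: seedling height-class marking shares observed in the field
_SEEDLING_SHARES = (0.249, 0.348, 0.336, 0.067)

_AMBIENT_R = (
    (1.00, 0.46, -0.19, -0.56),
    (0.46, 1.00, -0.43, -0.39),
    (-0.19, -0.43, 1.00, 0.27),
    (-0.56, -0.39, 0.27, 1.00),
)
_ADDITION_R = (
    (1.00, 0.43, -0.53, -0.63),
    (0.43, 1.00, -0.56, -0.43),
    (-0.53, -0.56, 1.00, 0.58),
    (-0.63, -0.43, 0.58, 1.00),
)


@dataclass
class SyntheticParams:
    """Generating parameters; defaults are the study conditions.

    Trait order everywhere: height (mm), leaf count, SLA (mm^2 mg^-1),
    flowering day (day of year).
    """

    n_plots: int = 6
    n_per_subplot: int = 100
    trait_means: dict = field(
        default_factory=lambda: {
            "ambient": (262.0, 5.32, 28.0, 213.0),
            "addition": (397.0, 6.05, 31.1, 217.0),
        }
    )
    trait_sds: dict = field(
        default_factory=lambda: {
            "ambient": (100.0, 1.6, 6.0, 8.0),
            "addition": (140.0, 1.8, 6.5, 8.0),
        }
    )
    trait_correlations: dict = field(
        default_factory=lambda: {"ambient": _AMBIENT_R, "addition": _ADDITION_R}
    )
    #: survival-to-fruiting intercepts on the logit scale (~84.3% / 81.5%)
    survival_logit: dict = field(
        default_factory=lambda: {"ambient": 1.681, "addition": 1.483}
    )
    #: survival-part coefficients = this scale x selection_gradients
    survival_gradient_scale: float = 0.3
    #: log mean fecundity of survivors (exp: ~28.9 / ~106 fruits)
    fecundity_log_mean: dict = field(
        default_factory=lambda: {"ambient": 3.364, "addition": 4.663}
    )
    nb_dispersion: float = 0.8  # NB shape k: var = mu + mu^2/k
    selection_gradients: dict = field(
        default_factory=lambda: {
            "ambient": (0.93, 0.41, -0.05, 0.21),
            "addition": (0.97, 0.28, -0.23, 0.29),
        }
    )
    plot_sd: float = 0.25  # trait-mean shifts, within-treatment SD units
    subplot_sd: float = 0.10
    fecundity_plot_sd: float = 0.30  # log-fecundity intercept shifts
    fecundity_subplot_sd: float = 0.15
    herbivory_rate: dict = field(
        default_factory=lambda: {"ambient": 0.13, "addition": 0.18}
    )
    anpp_mean: dict = field(
        default_factory=lambda: {"ambient": 430.0, "addition": 900.0}
    )
    anpp_cv: float = 0.15
    anpp_plot_sd: float = 0.10  # lognormal plot multiplier SD
    n_species: int = 10
    dirichlet_alpha: dict = field(
        default_factory=lambda: {"ambient": 1.2, "addition": 0.35}
    )
    harvest_area: float = 1.0
    par_top: float = 1800.0  # micromol m^-2 s^-1 above the canopy
    canopy_height: dict = field(
        default_factory=lambda: {"ambient": 120.0, "addition": 180.0}
    )
    par_decay: dict = field(
        default_factory=lambda: {"ambient": 0.020, "addition": 0.035}
    )  # ln(PAR) per cm
    par_noise_sd: float = 0.08
    exclusion_rate: float = 0.026  # handling-error fitness exclusions
    flowering_missing_if_dead: float = 0.6
    surface: str = "hurdle"  # or "lognormal"
    lognormal_noise_sd: float = 0.5

    def validate(self) -> None:
        for trt in TREATMENTS:
            R = np.asarray(self.trait_correlations[trt], float)
            if not np.allclose(R, R.T):
                raise ValueError(f"{trt} correlation matrix not symmetric")
            try:
                np.linalg.cholesky(R)
            except np.linalg.LinAlgError:
                raise ValueError(f"{trt} correlation matrix not positive definite")
            if not 0 < self.herbivory_rate[trt] < 1:
                raise ValueError("herbivory rates must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.surface not in ("hurdle", "lognormal"):
            raise ValueError(f"unknown surface {self.surface!r}")


@dataclass
class SyntheticStudy:
    individuals: pd.DataFrame
    community: pd.DataFrame
    par: pd.DataFrame
    design: StudyDesign
    ground_truth: dict


def expected_differentials(params: SyntheticParams) -> dict[str, np.ndarray]:
    """First-order oracle: S = R beta per treatment.

    Exact for a linear (or lognormal) fitness surface on standardized
    multivariate-normal traits.
    """
    out = {}
    for trt in TREATMENTS:
        R = np.asarray(params.trait_correlations[trt], float)
        beta = np.asarray(params.selection_gradients[trt], float)
        out[trt] = R @ beta
    return out


def mc_total_gradients(
    params: SyntheticParams, n: int = 500_000, seed: int = 0,
    *, complete_case: bool = False
) -> dict[str, np.ndarray]:
    """Brute-force ground truth for the total (linear) selection gradients.

    Selection enters the hurdle surface through both the survival logit and
    the log fecundity mean, and the zero-truncated draw inflates low means
    by 1/(1 - p0), so the realized gradient of relative fitness on z is not
    the fecundity-part coefficient vector.  This oracle simulates a large
    trait sample per treatment, forms the conditional mean fitness

        E[W | z, survival] = survival * mu(z) / (1 - p0(mu(z)))

    (count noise is mean-zero given z and survival, so it cannot move the
    slope), relativizes over everyone, and regresses on z — the estimand the
    pipeline estimates.

    With ``complete_case=True`` the regression is restricted to individuals
    that would enter the joint (all-traits) model: plants dead before
    flowering lack a flowering date and drop out of complete-case fits, so
    the complete-case estimand conditions partly on survival.  Relative
    fitness is still normalized over the full fitness-eligible sample, as in
    the pipeline.
    """
    out = {}
    k = params.nb_dispersion
    for trt in TREATMENTS:
        rng = np.random.default_rng([seed, 7, TREATMENTS.index(trt)])
        R = np.asarray(params.trait_correlations[trt], float)
        beta = np.asarray(params.selection_gradients[trt], float)
        z = rng.standard_normal((n, 4)) @ np.linalg.cholesky(R).T
        lin = z @ beta
        if params.surface == "lognormal":
            m = np.exp(lin)
            included = np.ones(n, dtype=bool)
        else:
            p_surv = expit(
                params.survival_logit[trt] + params.survival_gradient_scale * lin
            )
            survived = rng.random(n) < p_surv
            correction = 0.5 * (
                float(beta @ R @ beta)
                + params.fecundity_plot_sd**2
                + params.fecundity_subplot_sd**2
            )
            mu = np.exp(params.fecundity_log_mean[trt] - correction + lin)
            p0 = (k / (k + mu)) ** k
            m = np.where(survived, mu / (1 - p0), 0.0)
            included = survived | (
                rng.random(n) >= params.flowering_missing_if_dead
            )
        if not complete_case:
            included = np.ones(n, dtype=bool)
        w = m / m.mean()
        X = np.column_stack([np.ones(n), z])
        out[trt] = np.linalg.lstsq(X[included], w[included], rcond=None)[0][1:]
    return out


def hurdle_nb_moments(p_survive: float, mu: float, k: float) -> tuple[float, float]:
    """Closed-form marginal mean and variance of hurdle-ZTNB fitness
    (no trait dependence): W = 0 with prob 1-p, else zero-truncated NB."""
    p0 = (k / (k + mu)) ** k
    m1 = mu / (1 - p0)
    m2 = (mu + mu**2 / k + mu**2) / (1 - p0)
    mean = p_survive * m1
    var = p_survive * m2 - mean**2
    return mean, var


def _ztnb_draw(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Vectorized zero-truncated negative binomial via rejection."""
    out = np.zeros(len(mu), dtype=float)
    todo = np.ones(len(mu), dtype=bool)
    p = k / (k + mu)
    for _ in range(1000):
        if not todo.any():
            break
        draw = rng.negative_binomial(k, p[todo])
        out[todo] = draw
        todo = out == 0
    out[out == 0] = 1.0  # astronomically unlikely; keeps the support honest
    return out


def _make_design(n_plots: int) -> StudyDesign:
    return StudyDesign(
        {
            f"P{i + 1}": {
                "ambient": f"P{i + 1}-amb",
                "addition": f"P{i + 1}-add",
            }
            for i in range(n_plots)
        }
    )


def generate_study(params: SyntheticParams, seed: int = 0) -> SyntheticStudy:
    """Generate one complete synthetic study.

    Returns the three data tables, the design, and a ground-truth dictionary
    holding every generating value (including the R beta expected
    differentials and per-subplot intercept shifts).
    """
    params.validate()
    rng = np.random.default_rng([seed, 0])
    design = _make_design(params.n_plots)
    n = params.n_per_subplot
    k = params.nb_dispersion

    chol = {
        trt: np.linalg.cholesky(np.asarray(params.trait_correlations[trt], float))
        for trt in TREATMENTS
    }

    ind_rows = []
    com_rows = []
    par_rows = []
    shifts: dict[str, dict] = {}
    for plot in design.plots:
        plot_trait_shift = rng.normal(0, params.plot_sd, size=4)
        plot_fec_shift = rng.normal(0, params.fecundity_plot_sd)
        anpp_plot_mult = float(np.exp(rng.normal(0, params.anpp_plot_sd)))
        for trt in TREATMENTS:
            sub = design.subplot_map[plot][trt]
            sub_trait_shift = rng.normal(0, params.subplot_sd, size=4)
            sub_fec_shift = rng.normal(0, params.fecundity_subplot_sd)
            sds = np.asarray(params.trait_sds[trt], float)
            mu_vec = (
                np.asarray(params.trait_means[trt], float)
                + (plot_trait_shift + sub_trait_shift) * sds
            )
            beta = np.asarray(params.selection_gradients[trt], float)

            z = rng.standard_normal((n, 4)) @ chol[trt].T
            X = mu_vec + z * sds
            lin = z @ beta

            if params.surface == "lognormal":
                W = np.exp(lin + rng.normal(0, params.lognormal_noise_sd, n))
                survived = np.ones(n, dtype=bool)
            else:
                p_surv = expit(
                    params.survival_logit[trt] + params.survival_gradient_scale * lin
                )
                survived = rng.random(n) < p_surv
                # lognormal mean corrections keep the *marginal* survivor
                # fecundity at exp(fecundity_log_mean) despite the selection
                # term and the cluster intercept shifts
                correction = 0.5 * (
                    float(beta @ np.asarray(params.trait_correlations[trt]) @ beta)
                    + params.fecundity_plot_sd**2
                    + params.fecundity_subplot_sd**2
                )
                mu_f = np.exp(
                    params.fecundity_log_mean[trt] - correction
                    + plot_fec_shift + sub_fec_shift + lin
                )
                W = np.zeros(n)
                if survived.any():
                    W[survived] = _ztnb_draw(rng, mu_f[survived], k)

            herb = rng.random(n) < params.herbivory_rate[trt]
            excluded = rng.random(n) < params.exclusion_rate
            flowering = X[:, 3].copy()
            dead_missing = (~survived) & (
                rng.random(n) < params.flowering_missing_if_dead
            )
            flowering[dead_missing] = np.nan
            panicle = np.full(n, np.nan)
            pos = W > 0
            panicle[pos] = (
                30.0 * np.maximum(W[pos], 1e-9) ** 0.75
                * np.exp(rng.normal(0, 0.25, int(pos.sum())))
            )
            classes = rng.choice(
                SEEDLING_CLASSES, size=n, p=np.asarray(_SEEDLING_SHARES) / sum(_SEEDLING_SHARES)
            )
            fruit = W.astype(float)
            fruit[excluded] = np.nan
            for i in range(n):
                ind_rows.append(
                    {
                        "plot_id": plot,
                        "subplot_id": sub,
                        "treatment": trt,
                        "seedling_class": classes[i],
                        "height": max(X[i, 0], 1.0),
                        "leaf_count": max(round(X[i, 1]), 0),
                        "sla": max(X[i, 2], 1.0),
                        "flowering_day": flowering[i],
                        "fruit_count": fruit[i],
                        "main_panicle_length": panicle[i],
                        "herbivory": bool(herb[i]),
                        "fitness_excluded": bool(excluded[i]),
                    }
                )

            total_anpp = (
                params.anpp_mean[trt]
                * anpp_plot_mult
                * float(np.exp(rng.normal(0, params.anpp_cv)))
            )
            shares = rng.dirichlet(
                np.full(params.n_species, params.dirichlet_alpha[trt])
            )
            for s in range(params.n_species):
                com_rows.append(
                    {
                        "subplot_id": sub,
                        "species": f"sp{s + 1:02d}",
                        "biomass": shares[s] * total_anpp * params.harvest_area,
                        "harvest_area": params.harvest_area,
                    }
                )

            canopy = params.canopy_height[trt]
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                h = frac * canopy
                ln_par = (
                    np.log(params.par_top)
                    - params.par_decay[trt] * (canopy - h)
                    + rng.normal(0, params.par_noise_sd)
                )
                par_rows.append(
                    {"subplot_id": sub, "height": h, "par": float(np.exp(ln_par))}
                )
            shifts[sub] = {
                "trait_shift": (plot_trait_shift + sub_trait_shift).tolist(),
                "fecundity_shift": float(plot_fec_shift + sub_fec_shift),
            }

    individuals = pd.DataFrame(ind_rows)
    # raw z columns use the generating (not empirical) standardization; the
    # analysis re-standardizes, so only the raw traits are emitted.
    community = pd.DataFrame(com_rows)
    par = pd.DataFrame(par_rows)
    truth = {
        "params": asdict(params),
        "seed": seed,
        "expected_differentials": {
            trt: v.tolist() for trt, v in expected_differentials(params).items()
        },
        "selection_gradients": {
            trt: list(params.selection_gradients[trt]) for trt in TREATMENTS
        },
        "subplot_shifts": shifts,
        "traits": list(TRAITS),
    }
    return SyntheticStudy(individuals, community, par, design, truth)


@dataclass
class NullPermutationStudy:
    """Per-subplot response vectors and a predictor independent of them."""

    responses: pd.DataFrame  # subplot x 4 coefficient-like values
    predictor: pd.Series
    blocks: pd.Series


def generate_null_permutation_study(
    params: SyntheticParams, seed: int = 0
) -> NullPermutationStudy:
    """Null dataset for permutation/coverage calibration: subplot-level
    4-vectors with genuine plot structure, and a community-metric-like
    predictor drawn independently of them."""
    rng = np.random.default_rng([seed, 1])
    design = _make_design(params.n_plots)
    rows, pred, blocks = {}, {}, {}
    for plot in design.plots:
        plot_eff = rng.normal(0, 0.3, size=4)
        plot_pred = rng.normal(0, 0.3)
        for trt in TREATMENTS:
            sub = design.subplot_map[plot][trt]
            rows[sub] = plot_eff + rng.normal(0, 0.5, size=4)
            pred[sub] = plot_pred + rng.normal(0, 0.5)
            blocks[sub] = plot
    responses = pd.DataFrame.from_dict(rows, orient="index", columns=list(TRAITS)).sort_index()
    responses.index.name = "subplot_id"
    return NullPermutationStudy(
        responses,
        pd.Series(pred).sort_index(),
        pd.Series(blocks).sort_index(),
    )
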