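"""Phenotypic selection estimation (Lande–Arnold style) and fitness models.

Traits are z-scored **within subplots** (mean 0, sample SD 1) and fecundity
is relativized to a **within-subplot mean of one** (all fitness-eligible
individuals, zeros included), so selection is measured on the scale at which
individuals actually interact.

* **Selection differentials** ``S_i`` (total selection): slope from a
  separate mixed regression of relative fitness on each standardized trait,
  with subplot-level random slopes.
* **Selection gradients** ``beta_i`` (direct selection): partial slopes from
  one joint mixed regression on all four traits.
* **Nonlinear selection**: the full second-order surface; quadratic
  gradients are reported as twice the squared-term coefficient (recorded in
  the output), correlational gradients as the cross-term coefficients.

Two estimator backends share every contract: ``method="mixed"`` (statsmodels
MixedLM with a random intercept and independent random slopes per subplot;
per-subplot coefficients are fixed + conditional modes) and
``method="pooled"`` (closed-form OLS on the pooled standardized data —
because traits are centred within subplots this is the precision-weighted
average of subplot-wise regressions; it is also what each bootstrap
replicate can afford at scale).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from .core_data import TRAITS, DataError, apply_fitness_exclusions, survival
from .effects import EffectTest, FitError, binary_treatment_glmm, treatment_lmm, wald_chisq

#: Bonferroni family: four trait means
TRAIT_ALPHA = 0.05 / 4

#: variance-stabilizing transforms for trait-mean models (not for selection)
TRAIT_TRANSFORMS = {
    "height": "sqrt",
    "leaf_count": "sqrt",
    "sla": "log",
    "flowering_day": "log",
}

_COND_WARN = 1e6  # design condition number above which collinearity is flagged


@dataclass
class SelectionCoefficient:
    trait: str
    kind: str  # differential | gradient
    order: str  # linear | quadratic | correlational
    scope: str  # treatment label or subplot label
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = "mixed"
    notes: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return bool(self.ci_low > 0 or self.ci_high < 0)


def coefficients_frame(coeffs: list[SelectionCoefficient]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": c.trait,
                "kind": c.kind,
                "order": c.order,
                "scope": c.scope,
                "estimate": c.estimate,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "significant": c.significant,
                "method": c.method,
            }
            for c in coeffs
        ]
    )


# ---------------------------------------------------------------------------
# standardization / relativization


def standardize_traits(
    df: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    group: str = "subplot_id",
) -> pd.DataFrame:
    """Within-group z-scores (sample SD, ddof=1) as ``z_<trait>`` columns.

    Missing trait values stay missing.  A trait constant within a group (or
    with fewer than two values there) is an error naming both.
    """
    out = df.copy()
    for trait in traits:
        g = out.groupby(group)[trait]
        n = g.transform("count")
        mean = g.transform("mean")
        sd = g.transform("std")  # ddof=1
        short = out.loc[(n < 2) & out[trait].notna(), group]
        if len(short):
            raise DataError(
                f"trait {trait!r}: fewer than 2 values in subplot(s) "
                f"{sorted(short.unique())}"
            )
        degenerate = out.loc[(sd == 0) & out[trait].notna(), group]
        if len(degenerate):
            raise DataError(
                f"trait {trait!r} has zero variance in subplot(s) "
                f"{sorted(degenerate.unique())}"
            )
        out[f"z_{trait}"] = (out[trait] - mean) / sd
    return out


def relativize_fitness(df: pd.DataFrame, group: str = "subplot_id") -> pd.DataFrame:
    """Relative fitness ``w = W / mean(W)`` within group, zeros included.

    All fitness-eligible individuals enter the mean, survivors or not.
    """
    out = df.copy()
    W = out["fruit_count"]
    mean = out.groupby(group)["fruit_count"].transform("mean")
    zero_groups = out.loc[(mean <= 0) & W.notna(), group]
    if len(zero_groups):
        raise DataError(
            f"mean fitness is zero in subplot(s) {sorted(zero_groups.unique())}"
        )
    out["w"] = W / mean
    return out


def standardized_dataset(
    individuals: pd.DataFrame, traits: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Fitness-analysis dataset: exclusions applied, traits z-scored and
    fecundity relativized within subplots."""
    fitness, _ = apply_fitness_exclusions(individuals)
    fitness = fitness.dropna(subset=["fruit_count"])
    return relativize_fitness(standardize_traits(fitness, traits))


# ---------------------------------------------------------------------------
# estimator backends


def _pooled_ols(df: pd.DataFrame, zcols: list[str]) -> tuple[np.ndarray, float]:
    """OLS of w on [1, z...] over complete cases; returns (slopes, cond)."""
    sub = df.dropna(subset=zcols + ["w"])
    if len(sub) <= len(zcols) + 1:
        raise FitError("too few complete cases for pooled OLS")
    Z = sub[zcols].to_numpy(float)
    X = np.column_stack([np.ones(len(Z)), Z])
    beta, *_ = np.linalg.lstsq(X, sub["w"].to_numpy(float), rcond=None)
    return beta[1:], float(np.linalg.cond(X))


def _subplot_ols_slopes(df: pd.DataFrame, zcols: list[str]) -> pd.DataFrame:
    """Independent per-subplot OLS slopes (config alternative to BLUPs)."""
    rows = {}
    for sub, d in df.groupby("subplot_id"):
        try:
            slopes, _ = _pooled_ols(d, zcols)
        except FitError:
            slopes = np.full(len(zcols), np.nan)
        rows[sub] = slopes
    return pd.DataFrame.from_dict(rows, orient="index", columns=zcols).sort_index()


def _mixed_slopes(
    df: pd.DataFrame,
    zcols: list[str],
    *,
    random_intercept: bool = True,
    extra_fixed: list[str] | None = None,
) -> tuple[dict[str, float], pd.DataFrame, str]:
    """Mixed regression of w on standardized traits with subplot random
    slopes (independent, plus optional random intercept).

    Returns (fixed slopes, per-subplot conditional slopes, method label).
    Falls back to pooled OLS (flagged) when the mixed fit cannot converge or
    there are fewer than two subplots.
    """
    sub = df.dropna(subset=zcols + ["w"]).copy()
    fixed_terms = zcols + (extra_fixed or [])
    if sub["subplot_id"].nunique() < 2:
        slopes, _ = _pooled_ols(sub, zcols)
        fixed = dict(zip(zcols, slopes))
        per = pd.DataFrame(
            {c: [fixed[c]] for c in zcols}, index=sorted(sub["subplot_id"].unique())
        )
        return fixed, per, "ols_single_group"
    vc = {f"s_{c}": f"0 + {c}" for c in zcols}
    re_formula = "1" if random_intercept else "0"
    formula = "w ~ " + " + ".join(fixed_terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                formula, data=sub, groups="subplot_id",
                re_formula=re_formula, vc_formula=vc,
            )
            res = model.fit(method=["lbfgs"], reml=True, maxiter=500)
        if not np.all(np.isfinite([res.params.get(c, np.nan) for c in zcols])):
            raise FitError("non-finite fixed slopes")
        fixed = {c: float(res.params[c]) for c in fixed_terms}
        per_rows = {}
        for subplot, re_vals in res.random_effects.items():
            row = {}
            for c in zcols:
                key = next((k for k in re_vals.index if f"s_{c}[" in k), None)
                row[c] = fixed[c] + (float(re_vals[key]) if key else 0.0)
            per_rows[subplot] = row
        per = pd.DataFrame.from_dict(per_rows, orient="index").sort_index()[zcols]
        return fixed, per, "mixed"
    except (FitError, np.linalg.LinAlgError, ValueError) as exc:
        slopes, _ = _pooled_ols(sub, zcols)
        fixed = dict(zip(zcols, slopes))
        per = _subplot_ols_slopes(sub, zcols)
        return fixed, per, "pooled_fallback"


def _estimate(
    dataset: pd.DataFrame,
    traits: tuple[str, ...],
    *,
    joint: bool,
    kind: str,
    method: str,
    per_subplot: str = "conditional",
) -> tuple[list[SelectionCoefficient], pd.DataFrame]:
    coeffs: list[SelectionCoefficient] = []
    per_frames = []
    for scope, d in dataset.groupby("treatment", observed=True):
        if joint:
            zcols = [f"z_{t}" for t in traits]
            if method == "pooled":
                slopes, cond = _pooled_ols(d, zcols)
                fixed = dict(zip(zcols, slopes))
                per = _subplot_ols_slopes(d, zcols)
                used = "pooled"
            else:
                fixed, per, used = _mixed_slopes(d, zcols)
                _, cond = _pooled_ols(d, zcols)
                if per_subplot == "subplot_ols":
                    per = _subplot_ols_slopes(d, zcols)
            notes = {"condition_number": cond}
            if cond > _COND_WARN:
                notes["collinearity_warning"] = True
            for t in traits:
                coeffs.append(
                    SelectionCoefficient(
                        t, kind, "linear", str(scope), fixed[f"z_{t}"],
                        method=used, notes=notes,
                    )
                )
        else:
            per = pd.DataFrame()
            for t in traits:
                zc = [f"z_{t}"]
                if method == "pooled":
                    slopes, _ = _pooled_ols(d, zc)
                    fixed = {zc[0]: slopes[0]}
                    p1 = _subplot_ols_slopes(d, zc)
                    used = "pooled"
                else:
                    fixed, p1, used = _mixed_slopes(d, zc)
                    if per_subplot == "subplot_ols":
                        p1 = _subplot_ols_slopes(d, zc)
                coeffs.append(
                    SelectionCoefficient(
                        t, kind, "linear", str(scope), fixed[zc[0]], method=used
                    )
                )
                per = p1 if per.empty else per.join(p1, how="outer")
        per = per.rename(columns={f"z_{t}": t for t in traits})
        per.insert(0, "treatment", str(scope))
        per_frames.append(per)
    per_all = pd.concat(per_frames)
    per_all.index.name = "subplot_id"
    return coeffs, per_all.reset_index()


def estimate_differentials(
    dataset: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    *,
    method: str = "mixed",
    per_subplot: str = "conditional",
) -> tuple[list[SelectionCoefficient], pd.DataFrame]:
    """Standardized linear selection differentials S_i per treatment.

    One regression per trait (each on that trait's available cases), subplot
    random slopes; per-subplot S_i are fixed + conditional modes (or
    independent subplot OLS fits when ``per_subplot="subplot_ols"``).
    """
    return _estimate(
        dataset, traits, joint=False, kind="differential",
        method=method, per_subplot=per_subplot,
    )


def estimate_gradients(
    dataset: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    *,
    method: str = "mixed",
    per_subplot: str = "conditional",
) -> tuple[list[SelectionCoefficient], pd.DataFrame]:
    """Standardized linear selection gradients beta_i per treatment.

    One joint regression on all traits (complete cases); a design condition
    number above 1e6 attaches a collinearity warning to the output.
    """
    return _estimate(
        dataset, traits, joint=True, kind="gradient",
        method=method, per_subplot=per_subplot,
    )


def estimate_nonlinear(
    dataset: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    *,
    method: str = "mixed",
) -> list[SelectionCoefficient]:
    """Quadratic and correlational selection gradients per treatment.

    Fits the full second-order surface (linear + squared + cross-products of
    the standardized traits).  Quadratic gradients are **twice** the
    squared-term coefficients (the doubling is recorded in ``notes``);
    correlational gradients are the cross-term coefficients.  Random
    structure: subplot random intercept and linear slopes.
    """
    d = dataset.copy()
    zcols = [f"z_{t}" for t in traits]
    sq_cols, cross_cols = [], []
    for t in traits:
        col = f"q_{t}"
        d[col] = d[f"z_{t}"] ** 2
        sq_cols.append(col)
    for a, b in itertools.combinations(traits, 2):
        col = f"x_{a}__{b}"
        d[col] = d[f"z_{a}"] * d[f"z_{b}"]
        cross_cols.append(col)
    coeffs: list[SelectionCoefficient] = []
    for scope, dd in d.groupby("treatment", observed=True):
        cols = zcols + sq_cols + cross_cols
        if method == "pooled":
            slopes, _ = _pooled_ols(dd, cols)
            fixed = dict(zip(cols, slopes))
            used = "pooled"
        else:
            fixed, _, used = _mixed_slopes(dd, zcols, extra_fixed=sq_cols + cross_cols)
        for t in traits:
            coeffs.append(
                SelectionCoefficient(
                    t, "gradient", "quadratic", str(scope),
                    2.0 * fixed[f"q_{t}"], method=used,
                    notes={"convention": "gamma_ii = 2 * squared-term coefficient"},
                )
            )
        for a, b in itertools.combinations(traits, 2):
            coeffs.append(
                SelectionCoefficient(
                    f"{a}:{b}", "gradient", "correlational", str(scope),
                    fixed[f"x_{a}__{b}"], method=used,
                )
            )
    return coeffs


# ---------------------------------------------------------------------------
# correlations and trait means


@dataclass
class CorrelationMatrix:
    scope: str
    matrix: pd.DataFrame  # trait x trait Pearson r
    n: pd.DataFrame  # pairwise-complete counts
    p: pd.DataFrame  # two-sided p-values

    def pair(self, a: str, b: str) -> tuple[float, int, float]:
        return (
            float(self.matrix.loc[a, b]),
            int(self.n.loc[a, b]),
            float(self.p.loc[a, b]),
        )

    def tidy(self) -> pd.DataFrame:
        traits = list(self.matrix.index)
        rows = []
        for a, b in itertools.combinations(traits, 2):
            r, n, p = self.pair(a, b)
            rows.append(
                {"scope": self.scope, "trait_a": a, "trait_b": b, "r": r, "n": n, "p": p}
            )
        return pd.DataFrame(rows)


def phenotypic_correlations(
    df: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    scope: str = "all",
    *,
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations on raw trait values.

    Any individual contributing two or more traits enters the relevant
    pairs; a pair with fewer than ``min_pairs`` complete observations is set
    to NaN (flagged missing) rather than refused.
    """
    sub = df[list(traits)]
    r = sub.corr(method="pearson", min_periods=min_pairs)
    n = pd.DataFrame(index=r.index, columns=r.columns, dtype=float)
    p = pd.DataFrame(index=r.index, columns=r.columns, dtype=float)
    for a in traits:
        for b in traits:
            nn = int(sub[[a, b]].dropna().shape[0])
            n.loc[a, b] = nn
            if a == b or nn < min_pairs or pd.isna(r.loc[a, b]):
                p.loc[a, b] = np.nan if a != b else 0.0
                continue
            rv = float(np.clip(r.loc[a, b], -1 + 1e-15, 1 - 1e-15))
            t = rv * np.sqrt((nn - 2) / (1 - rv**2))
            p.loc[a, b] = 2 * sps.t.sf(abs(t), nn - 2)
    return CorrelationMatrix(scope, r, n.astype(int), p)


def subplot_correlation_vectors(
    df: pd.DataFrame, traits: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Per-subplot vectors of the six pairwise trait correlations (the
    multivariate response for the correlation PERMANOVA)."""
    rows = {}
    for sub, d in df.groupby("subplot_id"):
        cm = phenotypic_correlations(d, traits, scope=str(sub))
        rows[sub] = {
            f"r_{a}__{b}": cm.matrix.loc[a, b]
            for a, b in itertools.combinations(traits, 2)
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "subplot_id"
    return out


def test_treatment_effect_on_trait(
    individuals: pd.DataFrame, trait: str
) -> EffectTest:
    """N-treatment LMM for one trait mean, random intercepts for plot and
    subplot, on the variance-stabilized scale (sqrt for height and leaf
    count, log for SLA and flowering date); EMMs back-transformed."""
    if trait not in TRAIT_TRANSFORMS:
        raise ValueError(f"unknown trait {trait!r}")
    tf = TRAIT_TRANSFORMS[trait]
    df = individuals.dropna(subset=[trait]).copy()
    if tf == "log" and (df[trait] <= 0).any():
        rows = df.index[df[trait] <= 0].tolist()[:10]
        raise DataError(f"nonpositive {trait!r} under log transform at rows {rows}")
    if tf == "sqrt" and (df[trait] < 0).any():
        rows = df.index[df[trait] < 0].tolist()[:10]
        raise DataError(f"negative {trait!r} under sqrt transform at rows {rows}")
    df["_resp"] = np.sqrt(df[trait]) if tf == "sqrt" else np.log(df[trait])
    test = treatment_lmm(
        df, "_resp", subplot_col="subplot_id", adjusted_alpha=TRAIT_ALPHA
    )
    test.response = trait
    if test.emm:
        back = {}
        for label, (m, se) in test.emm.items():
            if tf == "sqrt":
                back[label] = (m**2, abs(2 * m) * se)
            else:
                back[label] = (float(np.exp(m)), float(np.exp(m)) * se)
        test.extra["emm_transformed_scale"] = {
            k: {"mean": v[0], "se": v[1]} for k, v in test.emm.items()
        }
        test.extra["transform"] = tf
        test.emm = back
    return test


test_treatment_effect_on_trait.__test__ = False  # library API, not a pytest case


# ---------------------------------------------------------------------------
# vectorized pooled-backend cases bootstrap


def pooled_cases_bootstrap(
    df: pd.DataFrame,
    traits: tuple[str, ...],
    *,
    joint: bool,
    B: int = 1000,
    seed: int = 0,
    group: str = "subplot_id",
    scope: str = "",
):
    """Cases bootstrap of the pooled-OLS estimator, vectorized.

    Semantically identical to running :func:`foxsel.resampling.cases_bootstrap`
    with a pooled-backend estimator — same resampling law and the same
    ``default_rng([seed, replicate, group_index])`` stream hierarchy, so the
    two paths produce the same replicate draws — but standardization,
    relativization and the regression are done in numpy, which is what makes
    thousand-replicate ensembles affordable.  ``joint=True`` bootstraps the
    gradient vector (complete cases), ``joint=False`` the per-trait
    differentials (each trait's available cases).
    """
    from .resampling import BootstrapEnsemble, _group_positions

    base = df.reset_index(drop=True)
    positions = _group_positions(base, group)
    X = base[list(traits)].to_numpy(float)
    W = base["fruit_count"].to_numpy(float)
    k = len(traits)
    out = np.full((B, k), np.nan)
    for b in range(B):
        zs, ws = [], []
        failed = False
        for gi, pos in enumerate(positions):
            rng = np.random.default_rng([seed, b, gi])
            idx = pos[rng.integers(0, len(pos), size=len(pos))]
            xg = X[idx]
            wg = W[idx]
            mean = np.nanmean(xg, axis=0)
            sd = np.nanstd(xg, axis=0, ddof=1)
            if np.any(sd == 0):
                failed = True
                break
            wbar = wg.mean()
            if wbar <= 0:
                failed = True
                break
            zs.append((xg - mean) / sd)
            ws.append(wg / wbar)
        if failed:
            continue
        Z = np.vstack(zs)
        wv = np.concatenate(ws)
        if joint:
            ok = ~np.isnan(Z).any(axis=1)
            if ok.sum() <= k + 1:
                continue
            D = np.column_stack([np.ones(int(ok.sum())), Z[ok]])
            try:
                out[b] = np.linalg.solve(D.T @ D, D.T @ wv[ok])[1:]
            except np.linalg.LinAlgError:
                continue
        else:
            for j in range(k):
                z = Z[:, j]
                ok = ~np.isnan(z)
                if ok.sum() <= 2:
                    continue
                D = np.column_stack([np.ones(int(ok.sum())), z[ok]])
                out[b, j] = np.linalg.solve(D.T @ D, D.T @ wv[ok])[1]
    return BootstrapEnsemble(tuple(traits), out, B, seed, scope)


# ---------------------------------------------------------------------------
# hurdle fitness model


@dataclass
class HurdleFitnessResult:
    survival: EffectTest | None
    fecundity: EffectTest | None
    notes: list[str] = field(default_factory=list)


def fit_hurdle_fitness(individuals: pd.DataFrame) -> HurdleFitnessResult:
    """Two-part (hurdle) treatment model for zero-inflated fecundity.

    Zero part: survival to fruit production (``fruit_count > 0``) ~ treatment,
    binomial mixed model with plot/subplot random intercepts.  Non-zero part:
    fruit count of survivors ~ treatment, zero-truncated negative binomial
    (log link) with plot as a fixed blocking factor.  A degenerate part
    (no zeros, or no positives) is skipped with a note.
    """
    fitness, _ = apply_fitness_exclusions(individuals)
    fitness = fitness.dropna(subset=["fruit_count"]).copy()
    fitness["survived"] = survival(fitness)
    notes: list[str] = []

    surv_test = None
    if fitness["survived"].nunique() < 2:
        notes.append("survival part skipped: all individuals share one outcome")
    else:
        surv_test = binary_treatment_glmm(fitness, "survived", adjusted_alpha=0.05)
        surv_test.response = "survival"

    pos = fitness[fitness["fruit_count"] > 0]
    fec_test = None
    if len(pos) == 0:
        notes.append("fecundity part skipped: no positive fruit counts")
    elif pos["fruit_count"].nunique() == 1:
        c = float(pos["fruit_count"].iloc[0])
        fec_test = EffectTest(
            response="fecundity", predictor="treatment", estimate=0.0, se=np.nan,
            statistic=np.nan, df=1, p_value=np.nan, adjusted_alpha=0.05,
            method="degenerate_constant",
            emm={"ambient": (c, 0.0), "addition": (c, 0.0)},
        )
        notes.append("fecundity part degenerate: all survivors share one count")
    else:
        fec_test = _fit_truncated_nb(pos)
    return HurdleFitnessResult(surv_test, fec_test, notes)


def _fit_truncated_nb(pos: pd.DataFrame) -> EffectTest:
    y = pos["fruit_count"].to_numpy(float)
    trt = (pos["treatment"] == "addition").to_numpy(float)
    plots = sorted(pos["plot_id"].unique())
    cols = [np.ones(len(pos)), trt]
    names = ["const", "trt"]
    for p in plots[1:]:
        cols.append((pos["plot_id"] == p).to_numpy(float))
        names.append(f"plot_{p}")
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = TruncatedLFNegativeBinomialP(y, X, truncation=0)
        # warm-start at the Poisson GLM solution: the truncated-NB likelihood
        # is badly scaled from a cold start on overdispersed counts
        import statsmodels.api as sm

        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        res = None
        for kwargs in (
            {"start_params": np.r_[pois.params, 1.0], "maxiter": 1000},
            {"start_params": np.r_[pois.params, 1.0], "method": "bfgs", "maxiter": 2000},
            {"maxiter": 1000},
        ):
            try:
                cand = model.fit(disp=0, **kwargs)
                np.asarray(cand.cov_params())  # raises if unavailable
                res = cand
                break
            except Exception:
                continue
        if res is None:
            raise FitError("truncated NB fit failed to converge")
    b = np.asarray(res.params)[: X.shape[1]]
    se_trt = float(np.sqrt(np.asarray(res.cov_params())[1, 1]))
    stat, p_val = wald_chisq(float(b[1]), se_trt)
    # EMMs by marginal standardization over the observed plot distribution
    emm = {}
    for label, t in (("ambient", 0.0), ("addition", 1.0)):
        Xc = X.copy()
        Xc[:, 1] = t
        mu = res.predict(Xc, which="mean")
        emm[label] = (float(np.mean(mu)), float(np.mean(mu)) * se_trt)
    return EffectTest(
        response="fecundity", predictor="treatment", estimate=float(b[1]),
        se=se_trt, statistic=stat, df=1, p_value=p_val, adjusted_alpha=0.05,
        method="truncated_nb_plot_blocked",
        emm=emm,
        extra={"emm_ratio_addition_over_ambient": float(np.exp(b[1]))},
    )
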