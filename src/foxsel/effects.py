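"""Mixed-model fitting helpers shared across analysis stages.

Treatment and covariate effects throughout the pipeline follow one contract:
fit a (generalized) linear mixed model with the appropriate random terms for
the plot/subplot hierarchy, and report a Wald chi-square on the single fixed
coefficient of interest, its p-value, the family-wise Bonferroni-adjusted
alpha, and estimated marginal means (EMMs) where the response scale calls
for back-transformation.

Model fitting is delegated to statsmodels:

* Gaussian responses -> :class:`statsmodels.regression.mixed_linear_model.MixedLM`
* binary responses   -> :class:`statsmodels.genmod.bayes_mixed_glm.BinomialBayesMixedGLM`
  (variational fit), with a plot-blocked fixed-effects GLM fallback

Small designs (12 subplots) can defeat REML; every fitter records the method
actually used so a fallback is visible in the output rather than silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM
import statsmodels.api as sm


class FitError(Exception):
    """A model could not be fitted on the given data."""


@dataclass
class EffectTest:
    """Wald test of one fixed effect from a mixed model.

    ``estimate`` is the fixed coefficient (treatment contrast or covariate
    slope) on the model scale; ``emm`` maps group label -> (mean, SE) on the
    response scale when marginal means are meaningful for the test.
    """

    response: str
    predictor: str
    estimate: float
    se: float
    statistic: float  # Wald chi-square, 1 df unless stated
    df: int
    p_value: float
    adjusted_alpha: float
    method: str
    emm: dict[str, tuple[float, float]] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.adjusted_alpha)

    def as_dict(self) -> dict:
        d = {
            "response": self.response,
            "predictor": self.predictor,
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "adjusted_alpha": self.adjusted_alpha,
            "significant": self.significant,
            "method": self.method,
        }
        if self.emm is not None:
            d["emm"] = {k: {"mean": v[0], "se": v[1]} for k, v in self.emm.items()}
        d.update(self.extra)
        return d


def wald_chisq(
    estimate: float, se: float, t_df: int | None = None
) -> tuple[float, float]:
    """Wald chi-square (1 df) and p for a single coefficient.

    With ``t_df`` the p-value comes from a t reference with that many
    degrees of freedom instead of the chi-square: on subplot-level
    responses (12 values from 6 plots) the chi-square reference is
    anticonservative (measured size ~0.09 at nominal 0.05), while the
    paired-design t with plots-1 df restores calibration.
    """
    if se <= 0 or not np.isfinite(se):
        return np.nan, np.nan
    stat = (estimate / se) ** 2
    if t_df is not None:
        p = 2 * sps.t.sf(np.sqrt(stat), t_df)
    else:
        p = sps.chi2.sf(stat, 1)
    return float(stat), float(p)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: str,
    groups: str,
    *,
    vc: Mapping[str, str] | None = None,
    re_formula: str = "1",
) -> tuple[object, str]:
    """Fit a Gaussian LMM, returning ``(result, method_label)``.

    ``fixed`` is the RHS of the fixed-effect formula.  Falls back through
    optimizers; raises :class:`FitError` if nothing converges.
    """
    formula = f"{response} ~ {fixed}"
    model = MixedLM.from_formula(
        formula, data=data, groups=groups, re_formula=re_formula,
        vc_formula=dict(vc) if vc else None,
    )
    last = None
    for method in (["lbfgs"], ["bfgs"], ["cg", "powell"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method=method, reml=True, maxiter=500)
            if np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse.iloc[:1])):
                return res, "lmm"
        except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:  # pragma: no cover
            last = exc
    raise FitError(f"LMM failed to converge for {formula!r}: {last}")


def _paired_plot_test(
    data: pd.DataFrame, response: str, plot_col: str, trt_col: str
) -> EffectTest:
    """Paired (by plot) comparison, the stated fallback for tiny designs."""
    wide = data.pivot_table(index=plot_col, columns=trt_col, values=response)
    diff = (wide["addition"] - wide["ambient"]).dropna()
    n = len(diff)
    if n < 2:
        raise FitError("paired fallback needs >= 2 complete plots")
    est = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(n))
    stat, p = wald_chisq(est, se, t_df=n - 1)
    return EffectTest(
        response=response, predictor="treatment", estimate=est, se=se,
        statistic=stat, df=1, p_value=p, adjusted_alpha=0.05,
        method="paired_by_plot",
        emm={
            "ambient": (float(wide["ambient"].mean()), float(wide["ambient"].sem())),
            "addition": (float(wide["addition"].mean()), float(wide["addition"].sem())),
        },
    )


def treatment_lmm(
    data: pd.DataFrame,
    response: str,
    *,
    plot_col: str = "plot_id",
    trt_col: str = "treatment",
    subplot_col: str | None = None,
    adjusted_alpha: float = 0.05,
) -> EffectTest:
    """LMM of a response on N treatment with plot (and optionally subplot)
    random intercepts; Wald chi-square on the treatment contrast.

    For subplot-level responses (one value per subplot) the model has random
    intercepts for plot only.  If the mixed fit fails on the small design,
    falls back to a paired-by-plot comparison, flagged in ``method``.
    """
    df = data.dropna(subset=[response]).copy()
    if df[trt_col].nunique() < 2:
        raise FitError("both treatments must be present")
    if df[plot_col].nunique() < 2:
        raise FitError("fewer than 2 plots: variance components unidentifiable")
    df["_trt"] = (df[trt_col] == "addition").astype(float)
    vc = {"subplot": f"0 + C({subplot_col})"} if subplot_col else None
    # subplot-level responses (one row per plot x treatment cell) get the
    # calibrated paired-design t reference; individual-level data keep chi2
    subplot_level = int(df.groupby([plot_col, trt_col]).size().max()) == 1
    t_df = df[plot_col].nunique() - 1 if subplot_level else None
    try:
        res, _ = fit_lmm(df, response, "_trt", plot_col, vc=vc)
        est = float(res.params["_trt"])
        se = float(res.bse["_trt"])
        stat, p = wald_chisq(est, se, t_df=t_df)
        if not np.isfinite(p):
            raise FitError("degenerate Wald statistic")
        icc = _plot_variance_share(res)
        intercept = float(res.params["Intercept"])
        cov = np.asarray(res.cov_params().loc[["Intercept", "_trt"], ["Intercept", "_trt"]])
        se_amb = float(np.sqrt(cov[0, 0]))
        se_add = float(np.sqrt(cov.sum()))
        out = EffectTest(
            response=response, predictor="treatment", estimate=est, se=se,
            statistic=stat, df=1, p_value=p, adjusted_alpha=adjusted_alpha,
            method="lmm",
            emm={"ambient": (intercept, se_amb), "addition": (intercept + est, se_add)},
            extra={"plot_variance_share": icc},
        )
        return out
    except FitError:
        t = _paired_plot_test(
            df.groupby([plot_col, trt_col], as_index=False)[response].mean(),
            response, plot_col, trt_col,
        )
        t.adjusted_alpha = adjusted_alpha
        return t


def _plot_variance_share(res) -> float:
    """Share of non-fixed variance attributed to the grouping factor."""
    try:
        var_group = float(np.atleast_2d(res.cov_re)[0, 0])
    except Exception:
        var_group = 0.0
    var_resid = float(res.scale)
    vc_sum = 0.0
    if getattr(res, "vcomp", None) is not None:
        vc_sum = float(np.sum(res.vcomp))
    denom = var_group + var_resid + vc_sum
    return var_group / denom if denom > 0 else np.nan


def covariate_lmm(
    data: pd.DataFrame,
    response: str,
    covariate: str,
    *,
    plot_col: str = "plot_id",
    adjusted_alpha: float = 0.05,
) -> EffectTest:
    """LMM of a subplot-level response on a continuous subplot covariate,
    random intercepts for plot."""
    df = data.dropna(subset=[response, covariate]).copy()
    if df[covariate].nunique() < 2:
        raise FitError(f"covariate {covariate!r} is constant")
    try:
        res, _ = fit_lmm(df, response, covariate, plot_col)
        est = float(res.params[covariate])
        se = float(res.bse[covariate])
        method = "lmm"
        icc = _plot_variance_share(res)
    except FitError:
        # plot-demeaned OLS keeps the within-plot slope interpretable
        d = df.copy()
        for col in (response, covariate):
            d[col] = d[col] - d.groupby(plot_col)[col].transform("mean")
        x = d[covariate].to_numpy(float)
        y = d[response].to_numpy(float)
        slope, _, _, _, stderr = sps.linregress(x, y)
        est, se, method, icc = float(slope), float(stderr), "within_plot_ols", np.nan
    stat, p = wald_chisq(est, se, t_df=df[plot_col].nunique() - 1)
    return EffectTest(
        response=response, predictor=covariate, estimate=est, se=se,
        statistic=stat, df=1, p_value=p, adjusted_alpha=adjusted_alpha,
        method=method, extra={"plot_variance_share": icc},
    )


def binary_treatment_glmm(
    data: pd.DataFrame,
    response: str,
    *,
    plot_col: str = "plot_id",
    subplot_col: str = "subplot_id",
    trt_col: str = "treatment",
    adjusted_alpha: float = 0.05,
) -> EffectTest:
    """Binomial mixed model of an individual-level 0/1 response on treatment,
    random intercepts for plot and subplot; EMMs on the proportion scale.

    Fitted by variational Bayes; if that fails, falls back to a fixed-effects
    GLM with plot as a blocking factor (flagged in ``method``).
    """
    df = data.dropna(subset=[response]).copy()
    df["_y"] = df[response].astype(float)
    df["_trt"] = (df[trt_col] == "addition").astype(float)
    if df["_y"].nunique() < 2:
        raise FitError(f"binary response {response!r} is degenerate")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                "_y ~ _trt",
                {"plot": f"0 + C({plot_col})", "subplot": f"0 + C({subplot_col})"},
                df,
            )
            # the VB objective uses the legacy global RNG internally; pin it
            # so identical inputs give identical fits, and restore the state
            state = np.random.get_state()
            try:
                np.random.seed(0)
                res = model.fit_vb()
            finally:
                np.random.set_state(state)
        names = list(model.exog_names)
        i0, i1 = names.index("Intercept"), names.index("_trt")
        b0, b1 = float(res.fe_mean[i0]), float(res.fe_mean[i1])
        s0, s1 = float(res.fe_sd[i0]), float(res.fe_sd[i1])
        method = "binomial_glmm_vb"
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM.from_formula(
                f"_y ~ _trt + C({plot_col})", data=df, family=sm.families.Binomial()
            ).fit()
        b0 = float(glm.params["Intercept"])  # reference plot; contrast is what matters
        b1 = float(glm.params["_trt"])
        s0 = float(glm.bse["Intercept"])
        s1 = float(glm.bse["_trt"])
        method = "binomial_glm_plot_blocked"
    stat, p = wald_chisq(b1, s1)
    emm = {
        "ambient": (float(expit(b0)), float(expit(b0) * (1 - expit(b0)) * s0)),
        "addition": (
            float(expit(b0 + b1)),
            float(expit(b0 + b1) * (1 - expit(b0 + b1)) * np.hypot(s0, s1)),
        ),
    }
    return EffectTest(
        response=response, predictor="treatment", estimate=b1, se=s1,
        statistic=stat, df=1, p_value=p, adjusted_alpha=adjusted_alpha,
        method=method, emm=emm,
    )
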