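"""Opportunity for selection (I) and its treatment/community correlates.

I is the variance in relative fitness — identically, the variance in
absolute fitness divided by squared mean absolute fitness — computed per
subplot over all fitness-eligible individuals (zeros included).  It bounds
the strength of standardized selection on any trait, so comparing I across
treatments asks whether N changes the *scope* for selection rather than the
trait-specific pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DataError, StudyDesign, apply_fitness_exclusions
from .effects import EffectTest, covariate_lmm, treatment_lmm
from .resampling import PermanovaResult, permanova

#: Bonferroni family: three community-metric associations
ASSOC_ALPHA = 0.05 / 3


@dataclass
class OpportunityRecord:
    subplot_id: str
    n: int
    mean_W: float
    var_W: float  # sample variance (ddof=1)
    I: float

    def as_dict(self) -> dict:
        return {
            "subplot_id": self.subplot_id,
            "n": self.n,
            "mean_W": self.mean_W,
            "var_W": self.var_W,
            "I": self.I,
        }


def opportunity_for_selection(
    fruit_counts: np.ndarray | pd.Series, subplot_id: str = ""
) -> OpportunityRecord:
    """I for one subplot: var(W)/mean(W)^2 (= sample variance of W/mean(W)).

    Requires >= 2 fitness-eligible individuals and positive mean fitness;
    scale-invariant in W.
    """
    W = np.asarray(fruit_counts, dtype=float)
    W = W[~np.isnan(W)]
    if len(W) < 2:
        raise DataError(f"subplot {subplot_id!r}: need >= 2 individuals for I")
    mean = float(W.mean())
    if mean <= 0:
        raise DataError(f"subplot {subplot_id!r}: mean fitness must be > 0")
    var = float(W.var(ddof=1))
    return OpportunityRecord(subplot_id, len(W), mean, var, var / mean**2)


def opportunity_table(
    individuals: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Per-subplot opportunity records (fitness exclusions applied first)."""
    fitness, _ = apply_fitness_exclusions(individuals)
    fitness = fitness.dropna(subset=["fruit_count"])
    sub_plot = design.subplot_plot()
    sub_trt = design.subplot_treatment()
    rows = []
    for sub in design.subplots:
        W = fitness.loc[fitness["subplot_id"] == sub, "fruit_count"]
        rec = opportunity_for_selection(W.to_numpy(), sub)
        d = rec.as_dict()
        d["plot_id"] = sub_plot[sub]
        d["treatment"] = sub_trt[sub]
        rows.append(d)
    cols = ["subplot_id", "plot_id", "treatment", "n", "mean_W", "var_W", "I"]
    return pd.DataFrame(rows)[cols]


def test_treatment_effect_on_I(opp: pd.DataFrame) -> EffectTest:
    """LMM of I on N treatment with plot random intercepts.

    ``extra["plot_variance_share"]`` reports the share of the non-treatment
    variance attributed to plot (a variance-component ratio, convention
    noted in the output).
    """
    test = treatment_lmm(opp, "I", adjusted_alpha=0.05)
    test.extra["plot_variance_share_convention"] = (
        "var(plot) / (var(plot) + var(residual)) from the REML fit"
    )
    return test


test_treatment_effect_on_I.__test__ = False  # library API, not a pytest case


def associate_I_with_metric(
    opp: pd.DataFrame, metrics: pd.DataFrame, metric: str
) -> EffectTest:
    """LMM of I on one community metric (plot random intercepts),
    Bonferroni alpha = 0.05/3 for the three-metric family."""
    merged = opp.merge(
        metrics[["subplot_id", metric]], on="subplot_id", validate="1:1"
    )
    if merged[metric].isna().any():
        raise DataError(f"metric {metric!r} missing for some subplots")
    return covariate_lmm(merged, "I", metric, adjusted_alpha=ASSOC_ALPHA)


def selection_strength_vs_I(
    per_subplot_coeffs: pd.DataFrame,
    opp: pd.DataFrame,
    *,
    traits: tuple[str, ...],
    n_perm="auto",
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA of per-subplot |selection coefficient| vectors on I, with
    plot blocking.  Identical coefficient vectors across subplots surface as
    a 'no variation' error from the distance partition."""
    merged = per_subplot_coeffs.merge(
        opp[["subplot_id", "plot_id", "I"]], on="subplot_id", validate="1:1"
    ).sort_values("subplot_id")
    Y = merged[list(traits)].to_numpy(float)
    if np.isnan(Y).any():
        raise DataError("per-subplot coefficient vectors incomplete")
    return permanova(
        np.abs(Y),
        merged["I"].to_numpy(float),
        merged["plot_id"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hypothetical mean-fitness scenarios (documented constructors for tests)


def scenario_mean_increase_reduces_I(W: np.ndarray, shift: float) -> np.ndarray:
    """Raise every individual's fitness by the same absolute amount.

    Variance is unchanged while mean grows, so I strictly decreases —
    the classic prediction that enrichment relaxes the opportunity for
    selection when fitness gains are evenly spread in absolute terms.
    """
    return np.asarray(W, float) + float(shift)


def scenario_mean_increase_preserves_I(W: np.ndarray, factor: float) -> np.ndarray:
    """Scale every individual's fitness proportionally.

    Mean and SD grow together, so I is unchanged — proportional gains leave
    the opportunity for selection untouched.
    """
    return np.asarray(W, float) * float(factor)


def scenario_mean_increase_raises_I(W: np.ndarray, factor: float) -> np.ndarray:
    """Amplify deviations from the mean faster than the mean itself.

    Fitness gains accrue disproportionately to already-high-fitness
    individuals: W' = mean + factor * (W - mean) + 0.1 * mean * (factor - 1),
    so variance grows by factor^2 while the mean grows only slightly,
    increasing I for factor > 1.
    """
    W = np.asarray(W, float)
    m = W.mean()
    return m + float(factor) * (W - m) + 0.1 * m * (float(factor) - 1)
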