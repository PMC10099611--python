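"""Subplot-level community metrics and their N-treatment tests.

Four metrics summarize each subplot's community context:

* **ANPP** — total aboveground net primary productivity, summed species
  biomass divided by harvested area (g m^-2);
* **Shannon diversity** (H', nats) over species biomass shares;
* **light asymmetry** — the slope of ln(PAR) against measurement height
  (per cm): a steeper canopy light gradient means taller plants capture
  disproportionately more light;
* **herbivory intensity** — the proportion of focal individuals whose
  inflorescences were consumed.

Treatment effects on the three continuous metrics are tested with an LMM
(random intercepts for plot); herbivory with a binomial mixed model on the
individual presence/absence records (random intercepts for plot and
subplot).  All four share one Bonferroni family (alpha = 0.05/4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import DataError, StudyDesign
from .effects import EffectTest, binary_treatment_glmm, treatment_lmm

METRICS = ("anpp", "shannon_h", "light_asymmetry_beta", "herbivory_intensity")

#: Bonferroni family: four community metrics
ADJUSTED_ALPHA = 0.05 / 4


def total_anpp(community: pd.DataFrame) -> float:
    """Total ANPP (g m^-2) for one subplot: sum biomass / harvest area."""
    if len(community) == 0:
        raise DataError("no species rows for subplot")
    area = community["harvest_area"].iloc[0]
    if not np.allclose(community["harvest_area"], area):
        raise DataError("inconsistent harvest_area within subplot")
    if area <= 0:
        raise DataError("harvest_area must be > 0")
    return float(community["biomass"].sum() / area)


def shannon_diversity(community: pd.DataFrame) -> float:
    """Shannon–Wiener H' (nats) over species biomass shares.

    Zero-biomass species contribute nothing (p ln p -> 0).
    """
    b = community["biomass"].to_numpy(float)
    total = b.sum()
    if total <= 0:
        raise DataError("total biomass must be > 0 for diversity")
    p = b[b > 0] / total
    return float(-(p * np.log(p)).sum())


def light_asymmetry(par_profile: pd.DataFrame) -> float:
    """OLS slope of ln(PAR) on height (ln units per cm) for one subplot.

    Invariant to multiplicative rescaling of PAR (the intercept absorbs it).
    """
    h = par_profile["height"].to_numpy(float)
    par = par_profile["par"].to_numpy(float)
    if np.unique(h).size < 2:
        raise DataError("need >= 2 distinct heights for the PAR regression")
    if np.any(par <= 0):
        raise DataError("PAR must be > 0 (log is taken)")
    slope = sps.linregress(h, np.log(par)).slope
    return float(slope)


def herbivory_intensity(individuals: pd.DataFrame) -> float:
    """Proportion of focal individuals with herbivory, one subplot."""
    if len(individuals) == 0:
        raise DataError("empty subplot")
    return float(individuals["herbivory"].mean())


def metrics_table(
    individuals: pd.DataFrame,
    community: pd.DataFrame,
    par: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Per-subplot table of the four community metrics."""
    sub_plot = design.subplot_plot()
    sub_trt = design.subplot_treatment()
    rows = []
    for sub in design.subplots:
        com = community[community["subplot_id"] == sub]
        prof = par[par["subplot_id"] == sub]
        ind = individuals[individuals["subplot_id"] == sub]
        rows.append(
            {
                "subplot_id": sub,
                "plot_id": sub_plot[sub],
                "treatment": sub_trt[sub],
                "anpp": total_anpp(com),
                "shannon_h": shannon_diversity(com),
                "light_asymmetry_beta": light_asymmetry(prof),
                "herbivory_intensity": herbivory_intensity(ind),
            }
        )
    return pd.DataFrame(rows)


def anpp_light_asymmetry_correlation(metrics: pd.DataFrame) -> tuple[float, float]:
    """Diagnostic Pearson r between ANPP and light asymmetry across subplots.

    When these are strongly collinear, only light asymmetry is carried into
    downstream covariate models.
    """
    r, p = sps.pearsonr(metrics["anpp"], metrics["light_asymmetry_beta"])
    return float(r), float(p)


def test_treatment_effect_on_metric(
    metrics: pd.DataFrame,
    metric: str,
    *,
    individuals: pd.DataFrame | None = None,
    design: StudyDesign | None = None,
) -> EffectTest:
    """N-treatment test for one community metric.

    Continuous metrics: LMM on subplot values, random intercepts for plot.
    Herbivory: binomial mixed model on individual presence/absence with
    random intercepts for plot and subplot (``individuals`` required).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "herbivory_intensity":
        if individuals is None or design is None:
            raise ValueError("herbivory test needs individual records and the design")
        df = individuals.copy()
        df["herbivory01"] = df["herbivory"].astype(float)
        return binary_treatment_glmm(
            df, "herbivory01", adjusted_alpha=ADJUSTED_ALPHA
        )
    return treatment_lmm(metrics, metric, adjusted_alpha=ADJUSTED_ALPHA)


test_treatment_effect_on_metric.__test__ = False  # library API, not a pytest case


def test_all_metrics(
    metrics: pd.DataFrame,
    individuals: pd.DataFrame,
    design: StudyDesign,
) -> dict[str, EffectTest]:
    return {
        m: test_treatment_effect_on_metric(
            metrics, m, individuals=individuals, design=design
        )
        for m in METRICS
    }


test_all_metrics.__test__ = False  # library API, not a pytest case
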