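"""Standardization, relativization, selection estimators, correlations,
trait-mean tests, and the hurdle fitness model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foxsel.core_data import TRAITS, DataError
from foxsel.selection import (
    estimate_differentials,
    estimate_gradients,
    estimate_nonlinear,
    fit_hurdle_fitness,
    phenotypic_correlations,
    relativize_fitness,
    standardize_traits,
    standardized_dataset,
    subplot_correlation_vectors,
    test_treatment_effect_on_trait,
    TRAIT_ALPHA,
)
from foxsel.synthetic import SyntheticParams, generate_study
from tests.conftest import make_individuals


def linear_surface_dataset(slope=0.5, n_subplots=4, n=25, seed=0, noise=0.0):
    """w constructed exactly (or nearly) as 1 + slope*z within subplots."""
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subplots):
        plot = f"P{s // 2 + 1}"
        trt = "ambient" if s % 2 == 0 else "addition"
        x = rng.normal(100 + 10 * s, 15, n)
        z = (x - x.mean()) / x.std(ddof=1)
        w = 1 + slope * z + (rng.normal(0, noise, n) if noise else 0.0)
        df = make_individuals(
            [(plot, f"S{s}", trt, x[i], 1.0) for i in range(n)]
        )
        df["height"] = x
        df["fruit_count"] = w * 10  # relativization rescales back to w
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestStandardize:
    def test_hand_computed_z_scores(self):
        df = make_individuals(
            [("P1", "S1", "ambient", h, 1.0) for h in (1.0, 2.0, 3.0, 4.0)]
        )
        out = standardize_traits(df, ("height",))
        expected = np.array([-1.161895, -0.387298, 0.387298, 1.161895])
        np.testing.assert_allclose(out["z_height"], expected, atol=1e-6)

    def test_idempotent_on_standardized_input(self):
        df = make_individuals(
            [("P1", "S1", "ambient", h, 1.0) for h in (-1.0, 0.0, 1.0)]
        )
        df["height"] = [-1.0, 0.0, 1.0]
        out = standardize_traits(df, ("height",))
        np.testing.assert_allclose(out["z_height"], df["height"], atol=1e-12)

    def test_constant_trait_names_subplot(self):
        df = make_individuals(
            [("P1", "S1", "ambient", 5.0, 1.0)] * 3
        )
        with pytest.raises(DataError, match="S1"):
            standardize_traits(df, ("height",))

    def test_missing_values_stay_missing(self):
        df = make_individuals(
            [("P1", "S1", "ambient", h, 1.0) for h in (1.0, 2.0, 3.0)]
        )
        df.loc[1, "height"] = np.nan
        out = standardize_traits(df, ("height",))
        assert np.isnan(out.loc[1, "z_height"]) and out["z_height"].notna().sum() == 2


class TestRelativize:
    def test_zeros_retained_and_mean_one(self):
        df = make_individuals(
            [("P1", "S1", "ambient", 100, w) for w in (0.0, 10.0, 20.0)]
        )
        out = relativize_fitness(df)
        np.testing.assert_allclose(out["w"], [0.0, 1.0, 2.0])

    def test_equal_fitness_gives_all_ones(self):
        df = make_individuals([("P1", "S1", "ambient", 100, 7.0)] * 4)
        np.testing.assert_allclose(relativize_fitness(df)["w"], 1.0)

    @given(st.floats(0.1, 100))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        df = make_individuals(
            [("P1", "S1", "ambient", 100, w) for w in (0.0, 3.0, 9.0)]
        )
        base = relativize_fitness(df)["w"]
        scaled = relativize_fitness(df.assign(fruit_count=df["fruit_count"] * c))["w"]
        np.testing.assert_allclose(base, scaled, rtol=1e-12)

    def test_all_zero_subplot_is_error(self):
        df = make_individuals([("P1", "S1", "ambient", 100, 0.0)] * 3)
        with pytest.raises(DataError):
            relativize_fitness(df)


class TestInvariants:
    def test_standardized_dataset_invariants_hold(self, small_study):
        sdf = standardized_dataset(small_study.individuals)
        for sub, d in sdf.groupby("subplot_id"):
            assert abs(d["w"].mean() - 1) < 1e-9
            for t in TRAITS:
                z = d[f"z_{t}"].dropna()
                if len(z) >= 2:
                    assert abs(z.mean()) < 1e-9
                    assert abs(z.std(ddof=1) - 1) < 1e-9


class TestDifferentials:
    @pytest.mark.parametrize("method", ["mixed", "pooled"])
    def test_exact_linear_surface(self, method):
        df = linear_surface_dataset(slope=0.5)
        sdf = relativize_fitness(standardize_traits(df, ("height",)))
        coeffs, per_sub = estimate_differentials(sdf, ("height",), method=method)
        for c in coeffs:
            assert c.estimate == pytest.approx(0.5, abs=1e-6)
        np.testing.assert_allclose(per_sub["height"], 0.5, atol=1e-6)

    def test_single_subplot_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 8, 40)
        w = 1 + 0.3 * (x - x.mean()) / x.std(ddof=1) + rng.normal(0, 0.4, 40)
        df = make_individuals([("P1", "S1", "ambient", x[i], 1.0) for i in range(40)])
        df["fruit_count"] = np.maximum(w, 0) * 5
        sdf = relativize_fitness(standardize_traits(df, ("height",)))
        # closed-form OLS oracle on the standardized data
        z = sdf["z_height"].to_numpy()
        wv = sdf["w"].to_numpy()
        X = np.column_stack([np.ones(len(z)), z])
        oracle = np.linalg.solve(X.T @ X, X.T @ wv)[1]
        coeffs, _ = estimate_differentials(sdf, ("height",), method="mixed")
        assert coeffs[0].estimate == pytest.approx(oracle, abs=1e-9)
        assert coeffs[0].method == "ols_single_group"

    def test_null_trait_near_zero(self):
        rng = np.random.default_rng(5)
        df = linear_surface_dataset(slope=0.0, n=400, noise=0.3, seed=9)
        sdf = relativize_fitness(standardize_traits(df, ("height",)))
        coeffs, _ = estimate_differentials(sdf, ("height",), method="pooled")
        for c in coeffs:
            assert abs(c.estimate) < 0.1


class TestGradients:
    def test_uncorrelated_traits_single_signal(self):
        rng = np.random.default_rng(8)
        n = 60
        frames = []
        for s in range(4):
            Z = rng.normal(size=(n, 4))
            Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
            w = 1 + 0.3 * Z[:, 0]
            df = make_individuals(
                [(f"P{s//2+1}", f"S{s}", "ambient" if s % 2 == 0 else "addition",
                  0.0, 1.0)] * n
            )
            for j, t in enumerate(TRAITS):
                df[t] = Z[:, j]
            df["fruit_count"] = w * 20
            frames.append(df)
        sdf = relativize_fitness(standardize_traits(pd.concat(frames, ignore_index=True)))
        coeffs, _ = estimate_gradients(sdf, method="pooled")
        for c in coeffs:
            expected = 0.3 if c.trait == "height" else 0.0
            assert c.estimate == pytest.approx(expected, abs=0.05)

    def test_correlated_traits_split_into_S_and_beta(self):
        # beta = (1, 0) with r = 0.5 -> S = (1, 0.5): differentials include
        # indirect selection, gradients do not
        rng = np.random.default_rng(12)
        n = 4000
        L = np.linalg.cholesky([[1, 0.5], [0.5, 1]])
        frames = []
        for s in range(2):
            Z = rng.normal(size=(n, 2)) @ L.T
            w = 1 + 1.0 * Z[:, 0]
            df = make_individuals([("P1", f"S{s}", "ambient", 0.0, 1.0)] * n)
            df["height"] = Z[:, 0]
            df["leaf_count"] = Z[:, 1]
            df["fruit_count"] = (w - w.min() + 0.01) * 10
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        traits = ("height", "leaf_count")
        sdf = relativize_fitness(standardize_traits(df, traits))
        scale = sdf.groupby("subplot_id")["w"].transform("mean")  # =1
        grads, _ = estimate_gradients(sdf, traits, method="pooled")
        diffs, _ = estimate_differentials(sdf, traits, method="pooled")
        g = {c.trait: c.estimate for c in grads}
        d = {c.trait: c.estimate for c in diffs}
        # relativization rescales w affinely; compare shape: ratios to height
        assert g["leaf_count"] / g["height"] == pytest.approx(0.0, abs=0.05)
        assert d["leaf_count"] / d["height"] == pytest.approx(0.5, abs=0.05)


class TestNonlinear:
    def test_pure_quadratic_surface_doubling_convention(self):
        rng = np.random.default_rng(21)
        frames = []
        for s in range(2):
            x = rng.normal(0, 1, 200)
            df = make_individuals([("P1", f"S{s}", "ambient", 0.0, 1.0)] * 200)
            df["height"] = x
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        sdf = standardize_traits(df, ("height",))
        sdf["w"] = 1 + sdf["z_height"] ** 2
        coeffs = estimate_nonlinear(sdf, ("height",), method="pooled")
        quad = [c for c in coeffs if c.order == "quadratic"][0]
        assert quad.estimate == pytest.approx(2.0, abs=1e-6)

    def test_pure_correlational_surface(self):
        rng = np.random.default_rng(22)
        frames = []
        for s in range(2):
            df = make_individuals([("P1", f"S{s}", "ambient", 0.0, 1.0)] * 300)
            df["height"] = rng.normal(0, 1, 300)
            df["leaf_count"] = rng.normal(0, 1, 300)
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        sdf = standardize_traits(df, ("height", "leaf_count"))
        sdf["w"] = 1 + 0.4 * sdf["z_height"] * sdf["z_leaf_count"]
        coeffs = estimate_nonlinear(sdf, ("height", "leaf_count"), method="pooled")
        cross = [c for c in coeffs if c.order == "correlational"][0]
        assert cross.estimate == pytest.approx(0.4, abs=0.02)
        quads = [c for c in coeffs if c.order == "quadratic"]
        for q in quads:
            assert abs(q.estimate) < 0.05

    def test_linear_surface_has_no_curvature(self):
        df = linear_surface_dataset(slope=0.5, n=100)
        sdf = relativize_fitness(standardize_traits(df, ("height",)))
        coeffs = estimate_nonlinear(sdf, ("height",), method="pooled")
        quad = [c for c in coeffs if c.order == "quadratic"][0]
        assert abs(quad.estimate) < 1e-6


class TestCorrelations:
    def test_duplicated_trait_correlates_perfectly(self):
        rng = np.random.default_rng(2)
        df = make_individuals(
            [("P1", "S1", "ambient", h, 1.0) for h in rng.normal(100, 10, 30)]
        )
        df["leaf_count"] = df["height"]
        cm = phenotypic_correlations(df, ("height", "leaf_count"))
        r, n, p = cm.pair("height", "leaf_count")
        assert r == pytest.approx(1.0) and n == 30

    def test_pairwise_complete_counts(self):
        df = make_individuals(
            [("P1", "S1", "ambient", float(i), 1.0) for i in range(10)]
        )
        df["leaf_count"] = df["height"] * 2 + np.arange(10) % 3
        df.loc[:3, "leaf_count"] = np.nan
        cm = phenotypic_correlations(df, ("height", "leaf_count"))
        _, n, _ = cm.pair("height", "leaf_count")
        assert n == 6

    def test_insufficient_pairs_flagged_missing(self):
        df = make_individuals(
            [("P1", "S1", "ambient", float(i), 1.0) for i in range(5)]
        )
        df["leaf_count"] = np.nan
        df.loc[0, "leaf_count"] = 1.0
        cm = phenotypic_correlations(df, ("height", "leaf_count"))
        assert np.isnan(cm.matrix.loc["height", "leaf_count"])

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(14)
        df = make_individuals(
            [("P1", "S1", "ambient", h, 1.0) for h in rng.normal(0, 1, 5000)]
        )
        df["leaf_count"] = rng.normal(0, 1, 5000)
        cm = phenotypic_correlations(df, ("height", "leaf_count"))
        r, _, _ = cm.pair("height", "leaf_count")
        assert abs(r) < 0.05

    def test_subplot_vectors_shape(self, small_study):
        vecs = subplot_correlation_vectors(small_study.individuals)
        assert vecs.shape == (12, 6)


class TestTraitMeans:
    def test_adjusted_alpha(self):
        assert TRAIT_ALPHA == pytest.approx(0.0125)

    def test_null_distribution_not_significant(self):
        rng = np.random.default_rng(31)
        rows = []
        for p in range(6):
            for trt, tag in (("ambient", "a"), ("addition", "b")):
                for i in range(30):
                    rows.append((f"P{p}", f"P{p}-{tag}", trt,
                                 rng.lognormal(5, 0.3), 1.0))
        df = make_individuals(rows)
        t = test_treatment_effect_on_trait(df, "height")
        assert t.p_value > 0.05

    def test_known_shift_recovered_via_emm_ratio(self):
        # multiplicative height shift: sqrt-scale location shift, EMM ratio
        rng = np.random.default_rng(32)
        rows = []
        for p in range(6):
            for trt, tag, mu in (("ambient", "a", 100.0), ("addition", "b", 150.0)):
                for i in range(80):
                    rows.append((f"P{p}", f"P{p}-{tag}", trt,
                                 mu * rng.lognormal(0, 0.05), 1.0))
        df = make_individuals(rows)
        t = test_treatment_effect_on_trait(df, "height")
        ratio = t.emm["addition"][0] / t.emm["ambient"][0]
        assert ratio == pytest.approx(1.5, rel=0.05)
        assert t.significant

    def test_nonpositive_under_log_is_error(self):
        df = make_individuals([("P1", "S1", "ambient", 100.0, 1.0)] * 5)
        df.loc[2, "sla"] = 0.0
        with pytest.raises(DataError, match="sla"):
            test_treatment_effect_on_trait(df, "sla")


class TestHurdle:
    def test_parameter_recovery_on_synthetic_hurdle(self):
        # survival ~84%/81%, fecundity means ~29/106: EMMs should recover
        study = generate_study(SyntheticParams(n_per_subplot=150), seed=99)
        res = fit_hurdle_fitness(study.individuals)
        assert res.survival is not None and res.fecundity is not None
        s_amb = res.survival.emm["ambient"][0]
        s_add = res.survival.emm["addition"][0]
        assert s_amb == pytest.approx(0.843, abs=0.06)
        assert s_add == pytest.approx(0.815, abs=0.06)
        ratio = res.fecundity.extra["emm_ratio_addition_over_ambient"]
        assert ratio == pytest.approx(106 / 28.9, rel=0.35)

    def test_treatment_fecundity_ratio_recovery(self):
        # 3x fecundity ratio injected -> EMM ratio ~ 3
        params = SyntheticParams(
            n_per_subplot=200,
            fecundity_log_mean={"ambient": 3.0, "addition": 3.0 + np.log(3.0)},
            selection_gradients={"ambient": (0, 0, 0, 0), "addition": (0, 0, 0, 0)},
            fecundity_plot_sd=0.0,
            fecundity_subplot_sd=0.0,
        )
        study = generate_study(params, seed=17)
        res = fit_hurdle_fitness(study.individuals)
        ratio = res.fecundity.extra["emm_ratio_addition_over_ambient"]
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_degenerate_parts_skipped(self):
        df = make_individuals([("P1", "S1", "ambient", 100.0, 5.0)] * 10
                              + [("P1", "S2", "addition", 100.0, 5.0)] * 10)
        res = fit_hurdle_fitness(df)
        assert res.survival is None
        assert res.fecundity.emm["ambient"][0] == 5.0
        assert any("survival part skipped" in n for n in res.notes)
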