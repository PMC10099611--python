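"""Cases bootstrap, percentile CIs, difference CIs, PERMANOVA, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from foxsel.resampling import (
    BootstrapEnsemble,
    ResamplingError,
    bonferroni_threshold,
    cases_bootstrap,
    percentile_ci,
    permanova,
    resample_within_groups,
    treatment_difference_ci,
)
from tests.conftest import make_individuals


def mean_estimator(df):
    return pd.Series({"m": df["height"].mean()})


class TestCasesBootstrap:
    def test_singleton_subplots_degenerate(self):
        # one individual per subplot: every resample is the original sample
        df = make_individuals(
            [("P1", f"S{i}", "ambient", float(10 + i), 1.0) for i in range(5)]
        )
        ens = cases_bootstrap(df, mean_estimator, B=150, seed=4)
        assert np.allclose(ens.replicates, df["height"].mean())

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(0)
        df = make_individuals(
            [("P1", f"S{i % 3}", "ambient", float(v), 1.0)
             for i, v in enumerate(rng.normal(50, 5, 30))]
        )
        a = cases_bootstrap(df, mean_estimator, B=120, seed=7)
        b = cases_bootstrap(df, mean_estimator, B=120, seed=7)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_different_seeds_differ(self):
        rng = np.random.default_rng(0)
        df = make_individuals(
            [("P1", f"S{i % 3}", "ambient", float(v), 1.0)
             for i, v in enumerate(rng.normal(50, 5, 30))]
        )
        a = cases_bootstrap(df, mean_estimator, B=120, seed=7)
        b = cases_bootstrap(df, mean_estimator, B=120, seed=8)
        assert not np.array_equal(a.replicates, b.replicates)

    def test_group_sizes_preserved(self):
        df = make_individuals(
            [("P1", f"S{i % 3}", "ambient", float(i), 1.0) for i in range(31)]
        )
        sample = resample_within_groups(df, seed=1, replicate=0)
        assert sample.groupby("subplot_id").size().to_dict() == \
            df.groupby("subplot_id").size().to_dict()

    def test_replicate_mean_near_point_estimate(self):
        rng = np.random.default_rng(1)
        df = make_individuals(
            [("P1", f"S{i % 4}", "ambient", float(v), 1.0)
             for i, v in enumerate(rng.normal(100, 10, 200))]
        )
        ens = cases_bootstrap(df, mean_estimator, B=200, seed=3)
        point = df["height"].mean()
        se = df["height"].std(ddof=1) / np.sqrt(len(df))
        assert abs(ens.successes().mean() - point) < 2 * se

    def test_failed_replicates_counted_and_flagged(self):
        calls = {"n": 0}

        def flaky(df):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise ValueError("synthetic failure")
            return pd.Series({"m": df["height"].mean()})

        df = make_individuals(
            [("P1", "S0", "ambient", float(i), 1.0) for i in range(10)]
        )
        ens = cases_bootstrap(df, flaky, B=120, seed=2)
        assert ens.failures > 0.05 * ens.B
        assert not ens.valid


class TestPercentileCI:
    def test_constant_replicates_collapse(self):
        ens = BootstrapEnsemble(("c",), np.full((200, 1), 3.14), 200, 0)
        lo, hi = percentile_ci(ens)
        assert lo[0] == hi[0] == pytest.approx(3.14)

    def test_quantile_oracle_on_1_to_1000(self):
        reps = np.arange(1.0, 1001.0)[:, None]
        ens = BootstrapEnsemble(("c",), reps, 1000, 0)
        lo, hi = percentile_ci(ens)
        # linear-interpolation quantile oracle: sort and index directly
        assert lo[0] == pytest.approx(np.quantile(reps, 0.025, method="linear"))
        assert hi[0] == pytest.approx(np.quantile(reps, 0.975, method="linear"))
        assert lo[0] == pytest.approx(1 + 0.025 * 999)
        assert hi[0] == pytest.approx(1 + 0.975 * 999)

    def test_symmetric_null_not_significant(self):
        rng = np.random.default_rng(5)
        reps = rng.normal(0, 1, size=(500, 1))
        ens = BootstrapEnsemble(("c",), reps, 500, 0)
        lo, hi = percentile_ci(ens)
        assert lo[0] < 0 < hi[0]

    def test_levels_are_nested(self):
        rng = np.random.default_rng(6)
        ens = BootstrapEnsemble(("c",), rng.normal(size=(400, 1)), 400, 0)
        lo95, hi95 = percentile_ci(ens, 0.95)
        lo80, hi80 = percentile_ci(ens, 0.80)
        assert lo95[0] <= lo80[0] and hi80[0] <= hi95[0]

    def test_too_few_replicates_is_error(self):
        ens = BootstrapEnsemble(("c",), np.zeros((50, 1)), 50, 0)
        with pytest.raises(ResamplingError):
            percentile_ci(ens)


class TestDifferenceCI:
    def test_identical_ensembles_give_zero_interval(self):
        reps = np.random.default_rng(0).normal(size=(300, 1))
        a = BootstrapEnsemble(("c",), reps.copy(), 300, 0)
        b = BootstrapEnsemble(("c",), reps.copy(), 300, 0)
        d = treatment_difference_ci(a, b)
        assert d.loc[0, "ci_low"] == d.loc[0, "ci_high"] == 0.0

    def test_constant_offset_recovered(self):
        reps = np.random.default_rng(1).normal(size=(300, 1))
        a = BootstrapEnsemble(("c",), reps, 300, 0)
        b = BootstrapEnsemble(("c",), reps + 0.7, 300, 0)
        d = treatment_difference_ci(a, b)
        assert d.loc[0, "difference_mean"] == pytest.approx(0.7)
        assert d.loc[0, "ci_low"] == pytest.approx(0.7)

    def test_mismatched_ids_rejected(self):
        a = BootstrapEnsemble(("x",), np.zeros((200, 1)), 200, 0)
        b = BootstrapEnsemble(("y",), np.zeros((200, 1)), 200, 0)
        with pytest.raises(ResamplingError):
            treatment_difference_ci(a, b)

    def test_failure_rows_dropped_pairwise(self):
        reps_a = np.random.default_rng(2).normal(size=(300, 1))
        reps_b = reps_a + 1.0
        reps_a[5] = np.nan
        reps_b[17] = np.nan
        a = BootstrapEnsemble(("c",), reps_a, 300, 0)
        b = BootstrapEnsemble(("c",), reps_b, 300, 0)
        d = treatment_difference_ci(a, b)
        assert d.loc[0, "n_pairs"] == 298


class TestPermanova:
    def test_univariate_unblocked_equals_anova_f(self):
        rng = np.random.default_rng(9)
        y = np.r_[rng.normal(0, 1, 10), rng.normal(1.2, 1, 10)]
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(y, groups, None, n_perm=99, seed=0)
        f_anova = sps.f_oneway(y[:10], y[10:]).statistic
        assert res.pseudo_F == pytest.approx(f_anova, abs=1e-9)
        assert (res.df_num, res.df_den) == (1, 18)

    def test_matches_scikit_bio_pseudo_f(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(10)
        Y = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(0.8, 1, (8, 3))])
        groups = ["a"] * 8 + ["b"] * 8
        res = permanova(Y, np.array(groups), None, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(squareform(pdist(Y)))
        ref = skbio_stats.permanova(dm, grouping=groups, permutations=0)
        assert res.pseudo_F == pytest.approx(float(ref["test statistic"]), abs=1e-9)

    def test_exhaustive_p_on_1_64_grid(self):
        rng = np.random.default_rng(11)
        blocks = np.repeat([f"P{i}" for i in range(6)], 2)
        pred = np.tile(["ambient", "addition"], 6)
        Y = rng.normal(0, 1, (12, 4))
        res = permanova(Y, pred, blocks, n_perm="exhaustive", seed=0)
        assert res.exhaustive and res.n_permutations == 64
        assert res.p_value >= 1 / 64
        assert (res.p_value * 64) == pytest.approx(round(res.p_value * 64))

    def test_signal_detected_at_floor_p(self):
        blocks = np.repeat([f"P{i}" for i in range(6)], 2)
        pred = np.tile(["ambient", "addition"], 6)
        Y = np.array([[0.0, 0], [5.0, 5]] * 6) + np.random.default_rng(3).normal(
            0, 0.01, (12, 2)
        )
        res = permanova(Y, pred, blocks, n_perm="exhaustive", seed=0)
        assert res.p_value == pytest.approx(1 / 64)

    def test_block_constant_structure_gives_p_one(self):
        # predictor identical within blocks; permutations cannot change F
        blocks = np.repeat([f"P{i}" for i in range(4)], 2)
        pred = np.repeat([0.0, 1.0, 2.0, 3.0], 2)
        Y = np.repeat([[0.0], [1.0], [2.0], [3.0]], 2, axis=0)
        Y = Y + np.random.default_rng(4).normal(0, 1e-6, Y.shape)
        res = permanova(Y, pred, blocks, n_perm="exhaustive", seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_identical_responses_is_error(self):
        with pytest.raises(ResamplingError):
            permanova(
                np.ones((12, 3)),
                np.tile(["a", "b"], 6),
                np.repeat(list("ABCDEF"), 2),
            )

    def test_continuous_predictor_univariate_matches_regression_f(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(0, 1, 15)
        res = permanova(y, x, None, n_perm=49, seed=0)
        lr = sps.linregress(x, y)
        f_reg = lr.rvalue**2 / (1 - lr.rvalue**2) * 13
        assert res.pseudo_F == pytest.approx(f_reg, rel=1e-9)


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,expected", [(1, 0.05), (3, 0.05 / 3), (4, 0.0125)]
    )
    def test_values(self, m, expected):
        assert bonferroni_threshold(0.05, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
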