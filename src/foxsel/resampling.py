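"""Resampling inference: clustered cases bootstrap and blocked PERMANOVA.

**Cases bootstrap.**  Selection-model residuals violate LMM assumptions, so
confidence intervals come from resampling whole individuals *within their
subplot* (cluster sizes preserved), re-standardizing traits and
re-relativizing fitness inside every replicate, and re-running the
estimator.  CIs are percentile; treatment contrasts are formed by pairing
replicate b of one treatment's ensemble with replicate b of the other
(the two ensembles are independent, so the per-index differences are draws
from the difference distribution).

**PERMANOVA.**  Pseudo-F on a Euclidean distance matrix in the
McArdle–Anderson trace form, which handles factor and continuous predictors
alike and reduces exactly to the one-way ANOVA F for a univariate two-group
response.  The permutation null shuffles the predictor *within plot blocks*;
with the study's six blocks of two subplots the full restricted set of
2^6 = 64 relabellings (identity included) is enumerated exhaustively, so the
smallest attainable p is 1/64.

Randomness: one integer seed drives a documented stream hierarchy — replicate
``b`` of subplot ``i`` uses ``default_rng([seed, b, i])`` — so ensembles are
reproducible independent of iteration order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


class ResamplingError(Exception):
    pass


# ---------------------------------------------------------------------------
# cases bootstrap


@dataclass
class BootstrapEnsemble:
    """Bootstrap replicate estimates for one or more coefficients.

    ``replicates`` has one row per attempted replicate (NaN rows mark
    estimator failures, preserving index pairing across treatments) and one
    column per coefficient id.
    """

    coefficient_ids: tuple[str, ...]
    replicates: np.ndarray  # (B, k), NaN rows = failed replicates
    B: int
    seed: int
    scope: str = ""

    @property
    def failures(self) -> int:
        return int(np.isnan(self.replicates).any(axis=1).sum())

    @property
    def valid(self) -> bool:
        return self.failures <= 0.05 * self.B

    def successes(self) -> np.ndarray:
        ok = ~np.isnan(self.replicates).any(axis=1)
        return self.replicates[ok]

    def summary(self, estimates: Sequence[float] | None = None, level: float = 0.95) -> pd.DataFrame:
        lo, hi = percentile_ci(self, level)
        rows = []
        for j, cid in enumerate(self.coefficient_ids):
            rows.append(
                {
                    "coefficient": cid,
                    "estimate": None if estimates is None else estimates[j],
                    "ci_low": lo[j],
                    "ci_high": hi[j],
                    "B": self.B,
                    "failures": self.failures,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _group_positions(df: pd.DataFrame, group: str) -> list[np.ndarray]:
    """Positional indices per group, in sorted group-label order."""
    codes = df[group].astype(str).to_numpy()
    return [np.flatnonzero(codes == lb) for lb in sorted(np.unique(codes))]


def resample_within_groups(
    df: pd.DataFrame, seed: int, replicate: int, group: str = "subplot_id"
) -> pd.DataFrame:
    """One cases-bootstrap resample: individuals drawn with replacement
    independently within every group, group sizes preserved.

    Replicate ``b`` of group ``i`` draws from ``default_rng([seed, b, i])``,
    so any replicate is reproducible in isolation.
    """
    positions = _group_positions(df, group)
    take = _resample_positions(positions, seed, replicate)
    return df.take(take).reset_index(drop=True)


def _resample_positions(
    positions: list[np.ndarray], seed: int, replicate: int
) -> np.ndarray:
    parts = []
    for gi, pos in enumerate(positions):
        rng = np.random.default_rng([seed, replicate, gi])
        parts.append(pos[rng.integers(0, len(pos), size=len(pos))])
    return np.concatenate(parts)


def cases_bootstrap(
    df: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], pd.Series],
    *,
    B: int = 1000,
    seed: int = 0,
    group: str = "subplot_id",
    scope: str = "",
) -> BootstrapEnsemble:
    """Clustered cases bootstrap of an estimator.

    ``estimator`` maps a raw resampled dataframe to a Series of coefficient
    estimates (it performs its own standardization/relativization so every
    replicate is a fresh analysis).  Replicates on which the estimator
    raises are recorded as NaN rows and counted as failures.
    """
    point = estimator(df)
    ids = tuple(point.index)
    out = np.full((B, len(ids)), np.nan)
    positions = _group_positions(df, group)
    base = df.reset_index(drop=True)
    for b in range(B):
        take = _resample_positions(positions, seed, b)
        sample = base.take(take).reset_index(drop=True)
        try:
            est = estimator(sample)
            out[b] = est.reindex(ids).to_numpy(float)
        except Exception:
            pass  # NaN row records the failure
    return BootstrapEnsemble(ids, out, B, seed, scope)


def percentile_ci(
    ensemble: BootstrapEnsemble | np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CI bounds (linear interpolation between order statistics).

    Requires at least 100 successful replicates.
    """
    reps = ensemble.successes() if isinstance(ensemble, BootstrapEnsemble) else np.asarray(ensemble)
    if reps.ndim == 1:
        reps = reps[:, None]
    if len(reps) < 100:
        raise ResamplingError(f"need >= 100 replicates for a percentile CI, have {len(reps)}")
    a = (1 - level) / 2
    lo = np.quantile(reps, a, axis=0, method="linear")
    hi = np.quantile(reps, 1 - a, axis=0, method="linear")
    return lo, hi


def treatment_difference_ci(
    ensemble_ambient: BootstrapEnsemble,
    ensemble_addition: BootstrapEnsemble,
    *,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile CI for addition − ambient coefficient differences.

    Replicates are paired by index; pairs where either side failed are
    dropped.  The point difference uses each ensemble's replicate means'
    ordering convention: the caller supplies point estimates separately via
    the coefficient tables; here we report the difference distribution.
    """
    if ensemble_ambient.coefficient_ids != ensemble_addition.coefficient_ids:
        raise ResamplingError(
            "coefficient ids differ between ensembles: "
            f"{ensemble_ambient.coefficient_ids} vs {ensemble_addition.coefficient_ids}"
        )
    if ensemble_ambient.B != ensemble_addition.B:
        raise ResamplingError("ensembles must have equal replicate counts")
    diff = ensemble_addition.replicates - ensemble_ambient.replicates
    ok = ~np.isnan(diff).any(axis=1)
    lo, hi = percentile_ci(diff[ok], level)
    rows = []
    for j, cid in enumerate(ensemble_ambient.coefficient_ids):
        rows.append(
            {
                "coefficient": cid,
                "difference_mean": float(np.mean(diff[ok, j])),
                "ci_low": float(lo[j]),
                "ci_high": float(hi[j]),
                "n_pairs": int(ok.sum()),
                "significant": bool(lo[j] > 0 or hi[j] < 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_num: int
    df_den: int
    p_value: float
    n_permutations: int
    blocking: str
    exhaustive: bool

    def as_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "blocking": self.blocking,
            "exhaustive": self.exhaustive,
        }


def _design_matrix(predictor: np.ndarray) -> np.ndarray:
    if predictor.dtype.kind in "OUS":
        levels = np.unique(predictor)
        cols = [np.ones(len(predictor))]
        for lv in levels[1:]:
            cols.append((predictor == lv).astype(float))
        return np.column_stack(cols)
    return np.column_stack([np.ones(len(predictor)), predictor.astype(float)])


def _pseudo_f(G: np.ndarray, X: np.ndarray) -> tuple[float, int, int]:
    n = len(G)
    Q, _ = np.linalg.qr(X)
    rank = X.shape[1]
    H = Q @ Q.T
    ss_total = float(np.trace(G))
    ss_model = float(np.trace(H @ G @ H))
    ss_resid = ss_total - ss_model
    df_num = rank - 1
    df_den = n - rank
    if df_num < 1 or df_den < 1 or ss_resid <= 0:
        raise ResamplingError("degenerate PERMANOVA partition")
    return (ss_model / df_num) / (ss_resid / df_den), df_num, df_den


def _block_permutations(blocks: np.ndarray, n_perm, rng: np.random.Generator):
    """Index permutations of the predictor restricted to within-block swaps.

    All blocks of size 2 and few enough blocks -> exhaustive enumeration of
    the 2^k restricted relabellings (identity included); otherwise
    ``n_perm`` sampled within-block shuffles.
    """
    labels = pd.unique(blocks)
    groups = [np.flatnonzero(blocks == lb) for lb in labels]
    sizes = [len(g) for g in groups]
    exhaustive = all(s == 2 for s in sizes) and 2 ** len(groups) <= 4096 and (
        n_perm == "auto" or n_perm == "exhaustive" or n_perm >= 2 ** len(groups)
    )
    n = len(blocks)
    if exhaustive:
        perms = []
        for flips in itertools.product((False, True), repeat=len(groups)):
            idx = np.arange(n)
            for g, fl in zip(groups, flips):
                if fl:
                    idx[g] = idx[g][::-1]
            perms.append(idx)
        return perms, True
    n_draws = 999 if n_perm in ("auto", "exhaustive") else int(n_perm)
    perms = []
    for _ in range(n_draws):
        idx = np.arange(n)
        for g in groups:
            idx[g] = rng.permutation(idx[g])
        perms.append(idx)
    return perms, False


def permanova(
    responses: pd.DataFrame | np.ndarray,
    predictor: Sequence,
    blocks: Sequence | None = None,
    *,
    n_perm="auto",
    seed: int = 0,
) -> PermanovaResult:
    """Blocked-permutation PERMANOVA of response vectors on one predictor.

    Euclidean distances; pseudo-F from the among/within partition of squared
    distances (trace form).  ``predictor`` may be a factor (strings) or a
    continuous covariate; significance permutes the predictor within
    ``blocks`` (freely when ``blocks`` is None).  Exhaustive p-values count
    the identity: ``p = #(F_perm >= F_obs) / n_perms``; sampled ones use the
    add-one rule ``(count + 1)/(n + 1)``.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    if np.allclose(pdist(Y), 0):
        raise ResamplingError("all response vectors identical: no variation to partition")
    pred = np.asarray(predictor)
    if len(pred) != n:
        raise ResamplingError("predictor length mismatch")
    D2 = squareform(pdist(Y, metric="sqeuclidean"))
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J

    X_obs = _design_matrix(pred)
    F_obs, df_num, df_den = _pseudo_f(G, X_obs)

    rng = np.random.default_rng(seed)
    if blocks is None:
        block_arr = np.zeros(n)
        blocking = "none"
    else:
        block_arr = np.asarray(blocks)
        blocking = "within-block"
    perms, exhaustive = _block_permutations(block_arr, n_perm, rng)
    count = 0
    for idx in perms:
        F_p, _, _ = _pseudo_f(G, _design_matrix(pred[idx]))
        if F_p >= F_obs - 1e-12:
            count += 1
    if exhaustive:
        p = count / len(perms)
    else:
        # identity is not among sampled perms; add-one keeps p > 0
        p = (count + 1) / (len(perms) + 1)
    return PermanovaResult(
        float(F_obs), df_num, df_den, float(p), len(perms), blocking, exhaustive
    )


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
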