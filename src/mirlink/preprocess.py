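"""Normalisation and differential-expression calling.

Implements the standard two-colour-array preprocessing chain on summarised
intensity matrices: floor-and-offset background subtraction (a documented
substitute for instrument-specific background models), log2 transformation,
quantile normalisation, and an empirical-Bayes moderated t-test with
Benjamini-Hochberg control of the false discovery rate.

The moderated test shrinks per-feature sample variances toward a pooled
prior.  The prior (d0, s0^2) is a scaled inverse-chi-square distribution
fitted by method of moments to the observed sample variances: marginally
s^2 ~ s0^2 * F(d, d0), whose first two moments identify d0 and s0^2.  The
moderated statistic uses the posterior variance
(d0*s0^2 + d*s^2)/(d0 + d) and t-distributed null with d + d0 degrees of
freedom; d0 -> 0 recovers the classical two-sample pooled t, d0 -> inf a
fully pooled z-like statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, TREATED, CONTROL


class PreprocessError(ValueError):
    pass


class ZeroVarianceWarning(UserWarning):
    """All features had zero within-group variance; moderation disabled."""


def background_correct(
    matrix: ExpressionMatrix,
    background: float = 0.0,
    floor: float = 0.5,
    offset: float = 16.0,
) -> ExpressionMatrix:
    """Floor-and-offset background subtraction on raw-scale intensities.

    Each cell becomes ``max(value - background, floor) + offset``; monotone
    in the input.  Requires non-negative raw intensities.
    """
    if floor < 0:
        raise PreprocessError("floor must be non-negative")
    vals = matrix.values.to_numpy()
    if (vals < 0).any():
        raise PreprocessError("background correction expects raw-scale values >= 0")
    out = np.maximum(vals - background, floor) + offset
    return matrix.with_values(out)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    vals = matrix.values.to_numpy()
    if (vals <= 0).any():
        raise PreprocessError("log2 transform requires positive values")
    return matrix.with_values(np.log2(vals))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column are resolved by averaging tied ranks, so tied input
    values receive the average of the quantile values they span.  A
    single-column matrix is returned unchanged.  Idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n, m = vals.shape
    if m < 2:
        return matrix.with_values(vals.copy())
    order_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, order_means)
    return matrix.with_values(out)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise PreprocessError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


@dataclass
class ModerationPrior:
    prior_df: float       # d0; np.inf means full pooling
    prior_var: float      # s0^2


def fit_variance_prior(sample_vars: np.ndarray, residual_df: int) -> ModerationPrior:
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    With s^2 | sigma^2 ~ sigma^2 chi^2_d / d and sigma^2 ~ d0 s0^2 / chi^2_d0,
    marginally s^2 / s0^2 ~ F(d, d0).  Matching the mean and variance of the
    observed s^2 yields d0 and s0^2.  When the observed dispersion does not
    exceed what sampling alone explains, d0 is infinite (full pooling).
    """
    s2 = np.asarray(sample_vars, dtype=float)
    s2 = s2[np.isfinite(s2)]
    d = float(residual_df)
    m1 = s2.mean()
    if m1 <= 0:
        return ModerationPrior(np.inf, max(m1, 0.0))
    ratio = s2.var(ddof=1) / m1**2 if s2.size > 1 else 0.0
    denom = ratio * d - 2.0
    if denom <= 0:
        return ModerationPrior(np.inf, m1)
    d0 = (2.0 * d - 4.0 + 4.0 * ratio * d) / denom
    if d0 <= 4.0:
        # Moment estimator valid only for d0 > 4; fall back to a heavy-tailed
        # but proper prior at the boundary.
        d0 = 4.0 + 1e-6
    s0 = m1 * (d0 - 2.0) / d0
    return ModerationPrior(d0, s0)


class DESelection(NamedTuple):
    all: list[str]
    up: list[str]
    down: list[str]


def moderated_t_test(
    matrix: ExpressionMatrix,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated two-sample t-test, treated vs. control.

    Returns a DataFrame with columns feature_id, log2_fc, t_stat, p_value,
    adj_p, direction.  ``prior_df`` overrides the estimated prior degrees of
    freedom (0 gives the classical pooled-variance t-test, ``np.inf`` full
    pooling).
    """
    xt = matrix.group_values(TREATED)
    xc = matrix.group_values(CONTROL)
    n1, n2 = xt.shape[1], xc.shape[1]
    if n1 < 2 or n2 < 2:
        raise PreprocessError("need >= 2 replicates per condition")
    d = n1 + n2 - 2
    mean_t = xt.mean(axis=1)
    mean_c = xc.mean(axis=1)
    log2_fc = mean_t - mean_c
    ss = ((xt - mean_t[:, None]) ** 2).sum(axis=1) + ((xc - mean_c[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / d

    if (s2 == 0).all():
        warnings.warn(
            "all features have zero within-group variance; "
            "falling back to unmoderated t",
            ZeroVarianceWarning,
        )
        prior = ModerationPrior(0.0, 0.0)
    elif prior_df is None:
        prior = fit_variance_prior(s2[s2 > 0], d)
    else:
        prior = ModerationPrior(float(prior_df), float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 0.0)

    if np.isinf(prior.prior_df):
        post_var = np.full_like(s2, prior.prior_var)
        df_total = np.inf
    elif prior.prior_df == 0:
        post_var = s2
        df_total = float(d)
    else:
        post_var = (prior.prior_df * prior.prior_var + d * s2) / (prior.prior_df + d)
        df_total = d + prior.prior_df

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log2_fc / se, np.where(log2_fc == 0, 0.0, np.inf * np.sign(log2_fc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(log2_fc >= 0, "up", "down"),
        }
    )


def select_de(results: pd.DataFrame, alpha: float = 0.05) -> DESelection:
    """Features with adjusted p below ``alpha``, partitioned by direction."""
    if len(results) == 0 or alpha <= 0:
        return DESelection([], [], [])
    hits = results[results["adj_p"] < alpha]
    up = hits.loc[hits["direction"] == "up", "feature_id"].tolist()
    down = hits.loc[hits["direction"] == "down", "feature_id"].tolist()
    return DESelection(hits["feature_id"].tolist(), up, down)
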