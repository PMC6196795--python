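"""Resampling-based significance for miRNA-mRNA association scores.

The null distribution of each candidate pair's score is built by decoupled
resampling: sample rows (arrays) of the miRNA matrix with replacement and,
independently, rows of the mRNA matrix, then rescore.  This destroys any
miRNA-mRNA coupling while preserving each side's marginal structure,
including its condition response, so the resulting p-value asks whether the
observed association exceeds what unrelated (possibly condition-responsive)
features produce.

Because plant miRNA regulation represses its targets (transcript cleavage),
the default alternative is one-sided in the repression direction: a pair is
significant when its score is more negative than the null.  A pair must
additionally be *repression-consistent* — its pooled within-condition
covariance must also be negative — which separates genuine regulation (whose
coupling acts inside each condition) from coincidental co-differential
expression (which correlates only through the treatment contrast).  The
classical two-sided |score| test without the consistency requirement is
available via ``alternative="two-sided"``.

P-values use the add-one estimator (never exactly zero); the FDR is
Benjamini-Hochberg over the candidate pairs only.  By default the null
draws are pooled across candidate pairs before computing p-values (the
scores are standardised, so the pairs' null distributions are
exchangeable): with B resamples and K pairs this gives a p-value
granularity of 1/(1+BK) instead of 1/(1+B), without which the
Benjamini-Hochberg step on heavily discretised p-values is unstable
(whether any pair survives the FDR threshold then hinges on how many pairs
tie at the minimum achievable p).  Per-pair nulls remain available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, TREATED, CONTROL
from .preprocess import bh_adjust
from .targets import CandidatePairSet

REPRESSION = "repression"
TWO_SIDED = "two-sided"


class SignificanceError(ValueError):
    pass


class UnstableNullWarning(UserWarning):
    """n_boot too small for stable p-values at the 0.01 level."""


@dataclass
class NullSamples:
    """Null score draws for candidate pairs: array (n_boot, n_pairs)."""

    pairs: list[tuple[str, str]]
    samples: np.ndarray
    method: str
    seed: int | None


def _pair_arrays(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix, candidates: CandidatePairSet
):
    if mirna.sample_ids != mrna.sample_ids:
        raise SignificanceError("miRNA and mRNA matrices must share samples")
    pairs = candidates.sorted_pairs()
    x = mirna.values.to_numpy(dtype=float).T  # N x p
    y = mrna.values.to_numpy(dtype=float).T  # N x m
    xi = {f: k for k, f in enumerate(mirna.feature_ids)}
    yi = {f: k for k, f in enumerate(mrna.feature_ids)}
    try:
        jj = np.array([xi[a] for a, _ in pairs], dtype=int)
        ii = np.array([yi[b] for _, b in pairs], dtype=int)
    except KeyError as exc:
        raise SignificanceError(f"candidate references unknown feature {exc}") from exc
    return pairs, x, y, jj, ii


def _pair_correlations(x: np.ndarray, y: np.ndarray, jj, ii) -> np.ndarray:
    """Standardised pairwise scores for selected (miRNA, mRNA) index pairs.

    Zero-variance columns (possible in bootstrap resamples) yield score 0.
    """
    n = x.shape[0]
    sx = x.std(axis=0, ddof=1)
    sy = y.std(axis=0, ddof=1)
    sx = np.where(sx == 0, np.inf, sx)
    sy = np.where(sy == 0, np.inf, sy)
    zx = (x - x.mean(axis=0)) / sx
    zy = (y - y.mean(axis=0)) / sy
    c = zx.T @ zy / (n - 1)
    return c[jj, ii]


def observed_scores(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix, candidates: CandidatePairSet
) -> pd.DataFrame:
    """Observed association score per candidate pair (pairwise convention)."""
    pairs, x, y, jj, ii = _pair_arrays(mirna, mrna, candidates)
    scores = _pair_correlations(x, y, jj, ii)
    return pd.DataFrame(
        {
            "mirna_id": [a for a, _ in pairs],
            "mrna_id": [b for _, b in pairs],
            "score": scores,
        }
    )


def resample_null(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    candidates: CandidatePairSet,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "decoupled",
) -> NullSamples:
    """Null score samples per candidate pair.

    ``method="decoupled"`` (default): rows of X and rows of Y are resampled
    with replacement independently, removing any X-Y coupling.
    ``method="case"``: paired rows are resampled together (case bootstrap);
    the draws then describe the sampling variability of the observed score
    rather than a null, for use with sign-stability p-values.
    """
    if n_boot < 1:
        raise SignificanceError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} gives unstable p-values at the 0.01 level",
            UnstableNullWarning,
        )
    if method not in ("decoupled", "case"):
        raise SignificanceError(f"unknown resampling method {method!r}")
    pairs, x, y, jj, ii = _pair_arrays(mirna, mrna, candidates)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty((n_boot, len(pairs)))
    for b in range(n_boot):
        ix = rng.integers(0, n, n)
        iy = ix if method == "case" else rng.integers(0, n, n)
        out[b] = _pair_correlations(x[ix], y[iy], jj, ii)
    return NullSamples(pairs=pairs, samples=out, method=method, seed=seed)


def empirical_p(
    observed: float | np.ndarray,
    null_samples: np.ndarray,
    alternative: str = TWO_SIDED,
) -> np.ndarray | float:
    """Add-one empirical p-value against null draws.

    two-sided: (1 + #{|null| >= |obs|}) / (1 + B);
    repression: (1 + #{null <= obs}) / (1 + B).
    """
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise SignificanceError("null_samples must be non-empty")
    obs = np.asarray(observed, dtype=float)
    scalar = obs.ndim == 0
    if null.ndim == 1:
        null = null[:, None]
    obs2 = np.atleast_1d(obs)
    if alternative == TWO_SIDED:
        count = (np.abs(null) >= np.abs(obs2)[None, :]).sum(axis=0)
    elif alternative == REPRESSION:
        count = (null <= obs2[None, :]).sum(axis=0)
    else:
        raise SignificanceError(f"unknown alternative {alternative!r}")
    p = (1.0 + count) / (1.0 + null.shape[0])
    return float(p[0]) if scalar else p


def within_condition_covariance(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix, candidates: CandidatePairSet
) -> np.ndarray:
    """Pooled within-condition covariance per candidate pair.

    Residuals around each condition's mean carry the coupling that acts
    inside conditions; co-differential expression alone leaves them
    uncorrelated.
    """
    pairs, x, y, jj, ii = _pair_arrays(mirna, mrna, candidates)
    xw = x.copy()
    yw = y.copy()
    cond = mirna.conditions.to_numpy()
    for label in (TREATED, CONTROL):
        mask = cond == label
        xw[mask] -= xw[mask].mean(axis=0)
        yw[mask] -= yw[mask].mean(axis=0)
    c = xw.T @ yw
    return c[jj, ii]


def pooled_empirical_p(
    observed: np.ndarray, null_samples: np.ndarray, alternative: str = TWO_SIDED
) -> np.ndarray:
    """Add-one p-values against the null draws pooled over all pairs."""
    pool = np.sort(np.asarray(null_samples, dtype=float).ravel())
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    total = pool.size
    if total == 0:
        raise SignificanceError("null_samples must be non-empty")
    if alternative == TWO_SIDED:
        apool = np.sort(np.abs(pool))
        count = total - np.searchsorted(apool, np.abs(obs), side="left")
    elif alternative == REPRESSION:
        count = np.searchsorted(pool, obs, side="right")
    else:
        raise SignificanceError(f"unknown alternative {alternative!r}")
    return (1.0 + count) / (1.0 + total)


def evaluate_pairs(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    candidates: CandidatePairSet,
    n_boot: int = 1000,
    seed: int | None = None,
    alternative: str = REPRESSION,
    method: str = "decoupled",
    pool_null: bool = True,
) -> pd.DataFrame:
    """Score candidate pairs and attach bootstrap p-values.

    Returns a DataFrame with columns mirna_id, mrna_id, score, b (=|score|),
    p_value and, for the repression alternative, within_cov.  With
    ``pool_null`` (default) p-values are computed against the null draws
    pooled over all candidate pairs; otherwise each pair uses only its own
    ``n_boot`` draws.
    """
    table = observed_scores(mirna, mrna, candidates)
    null = resample_null(mirna, mrna, candidates, n_boot=n_boot, seed=seed, method=method)
    table["b"] = table["score"].abs()
    pfun = pooled_empirical_p if pool_null else empirical_p
    table["p_value"] = pfun(
        table["score"].to_numpy(), null.samples, alternative=alternative
    )
    if alternative == REPRESSION:
        table["within_cov"] = within_condition_covariance(mirna, mrna, candidates)
    return table


def call_significant(
    pairs: pd.DataFrame,
    b_threshold: float = 0.8,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
    alternative: str = REPRESSION,
) -> pd.DataFrame:
    """Apply the triple threshold (b, p, FDR) and return all pairs annotated.

    FDR is Benjamini-Hochberg over the candidate pairs.  With the default
    repression alternative a pair must additionally have a negative score
    and be repression-consistent (negative within-condition covariance) if a
    ``within_cov`` column is present.  Output is sorted by b descending;
    the ``significant`` column flags the calls.
    """
    out = pairs.copy()
    if len(out) == 0:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = (
        (out["b"] > b_threshold)
        & (out["p_value"] < p_threshold)
        & (out["fdr"] < fdr_threshold)
    )
    if alternative == REPRESSION:
        sig &= out["score"] < 0
        if "within_cov" in out.columns:
            sig &= out["within_cov"] < 0
    out["significant"] = sig
    return out.sort_values(["b", "mirna_id", "mrna_id"], ascending=[False, True, True]).reset_index(
        drop=True
    )


def significant_pairs(called: pd.DataFrame) -> pd.DataFrame:
    return called[called["significant"]].reset_index(drop=True)
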