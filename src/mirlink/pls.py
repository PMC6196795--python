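"""Partial-least-squares association scoring between miRNAs and mRNAs.

For each response (mRNA) the predictor matrix (miRNAs) is decomposed into
``v`` orthogonal latent components; each component's coefficient is the
ordinary least-squares regression of the response on the component score,
and predictors/responses are mean-centred and unit-scaled (autoscaling)
before fitting so coefficients are dimensionless.

Two association-score conventions are provided:

``pairwise`` (default)
    The standardised single-predictor coefficient for each (mRNA, miRNA)
    pair — the single-predictor collapse of the latent-component regression,
    which equals the Pearson correlation of the autoscaled profiles.  This
    is the scale on which an absolute-score edge threshold such as 0.8 is
    meaningful, and the convention used by the downstream significance and
    network stages (negative score = putative repression).

``joint``
    The predictor-space coefficient of the joint multi-predictor PLS fit,
    mapped back from the latent components (B = W (P'W)^-1 q).  With many
    collinear predictors and few samples these coefficients are shrunk and
    spread across predictors; they rank associations but are not comparable
    to a correlation-scale threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .targets import CandidatePairSet


class PLSError(ValueError):
    pass


class ZeroVarianceError(PLSError):
    """A predictor or response column has zero sample variance."""


def _as_array(data, transpose_from_matrix: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, ExpressionMatrix):
        # stored features x samples; the regression wants samples x features
        return data.values.to_numpy(dtype=float).T, data.feature_ids
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"var{i}" for i in range(arr.shape[1])]


def autoscale(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre columns and scale to unit sample standard deviation."""
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.nonzero(sd == 0)[0]
        raise ZeroVarianceError(f"zero-variance columns at indices {bad.tolist()}")
    return (arr - mean) / sd, mean, sd


@dataclass
class PLSModel:
    """Per-response latent decomposition of the autoscaled predictors.

    Arrays are stacked over responses: ``x_weights``/``x_loadings`` have
    shape (m, v, p), ``y_loadings`` (m, v), ``scores`` (m, v, N),
    ``residuals`` (m, N).
    """

    n_components: int
    x_names: list[str]
    y_names: list[str]
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    residuals: np.ndarray
    x_sd: np.ndarray
    y_sd: np.ndarray
    x_mean: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)

    def coefficients(self) -> np.ndarray:
        """Standardised predictor-space coefficients, shape (m, p).

        Maps the latent-component coefficients back to the predictors:
        B = W (P'W)^{-1} q per response.
        """
        ptw = np.einsum("mvp,mwp->mvw", self.x_loadings, self.x_weights)
        sol = np.linalg.solve(ptw, self.y_loadings[:, :, None])
        return np.einsum("mvp,mv->mp", self.x_weights, sol[:, :, 0])


def fit_pls(X, Y, v: int = 3) -> PLSModel:
    """Fit per-response PLS regressions of every Y column on all X columns.

    ``X`` and ``Y`` are samples x features arrays, DataFrames, or
    ``ExpressionMatrix`` (transposed automatically); both are autoscaled.
    ``v`` latent components are extracted per response by the NIPALS
    deflation scheme; for a single response each component is closed-form
    (weight vector proportional to X'y), so no iteration is required.
    """
    x_arr, x_names = _as_array(X, True)
    y_arr, y_names = _as_array(Y, True)
    if x_arr.shape[0] != y_arr.shape[0]:
        raise PLSError("X and Y must share the sample dimension")
    n = x_arr.shape[0]
    if not 1 <= v < n:
        raise PLSError(f"n_components must satisfy 1 <= v < N (v={v}, N={n})")
    xs, x_mean, x_sd = autoscale(x_arr)
    ys, y_mean, y_sd = autoscale(y_arr)
    p = xs.shape[1]
    m = ys.shape[1]

    xr = np.broadcast_to(xs, (m, n, p)).copy()
    yr = ys.T.copy()  # m x N
    W = np.zeros((m, v, p))
    P = np.zeros((m, v, p))
    q = np.zeros((m, v))
    T = np.zeros((m, v, n))
    for l in range(v):
        w = np.einsum("mnp,mn->mp", xr, yr)
        norm = np.linalg.norm(w, axis=1, keepdims=True)
        safe = norm.copy()
        safe[safe == 0] = 1.0
        w /= safe
        t = np.einsum("mnp,mp->mn", xr, w)
        tt = (t * t).sum(axis=1)
        tt_safe = np.where(tt == 0, 1.0, tt)
        beta = (t * yr).sum(axis=1) / tt_safe
        pl = np.einsum("mnp,mn->mp", xr, t) / tt_safe[:, None]
        xr -= t[:, :, None] * pl[:, None, :]
        yr -= beta[:, None] * t
        W[:, l], P[:, l], q[:, l], T[:, l] = w, pl, beta, t
    return PLSModel(
        n_components=v,
        x_names=x_names,
        y_names=y_names,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        residuals=yr,
        x_sd=x_sd,
        y_sd=y_sd,
        x_mean=x_mean,
        y_mean=y_mean,
    )


@dataclass
class AssociationMatrix:
    """m x p matrix of association scores (rows mRNAs, columns miRNAs)."""

    scores: pd.DataFrame          # index = mRNA ids, columns = miRNA ids
    sd_x: pd.Series               # per-miRNA sample standard deviation
    sd_y: pd.Series               # per-mRNA sample standard deviation
    mode: str = "pairwise"

    def score(self, mirna_id: str, mrna_id: str) -> float:
        return float(self.scores.at[mrna_id, mirna_id])

    def to_tsv(self, path) -> None:
        frame = self.scores.copy()
        frame.index.name = "mrna_id"
        frame.to_csv(path, sep="\t", float_format="%.17g")


def association_scores(model: PLSModel, X, Y, mode: str = "pairwise") -> AssociationMatrix:
    """Association score matrix S[i, j] between mRNA i and miRNA j.

    Scores are standardised (unit-free, sign preserved; negative = putative
    repression): multiplying any input row by a positive constant leaves its
    scores unchanged, and negating a miRNA profile negates its score column.
    """
    x_arr, x_names = _as_array(X, True)
    y_arr, y_names = _as_array(Y, True)
    if x_names != model.x_names or y_names != model.y_names:
        raise PLSError("X/Y do not match the fitted model")
    if mode == "joint":
        scores = model.coefficients()
    elif mode == "pairwise":
        xs, _, _ = autoscale(x_arr)
        ys, _, _ = autoscale(y_arr)
        n = xs.shape[0]
        # single-predictor collapse: per pair, beta = t'y/t't with t = +/- x,
        # rescaled by sd ratios; equals the Pearson correlation.
        scores = (ys.T @ xs) / (n - 1)
    else:
        raise PLSError(f"unknown mode {mode!r}")
    frame = pd.DataFrame(scores, index=model.y_names, columns=model.x_names)
    return AssociationMatrix(
        scores=frame,
        sd_x=pd.Series(model.x_sd, index=model.x_names),
        sd_y=pd.Series(model.y_sd, index=model.y_names),
        mode=mode,
    )


def score_candidate_pairs(
    assoc: AssociationMatrix, candidates: CandidatePairSet
) -> pd.DataFrame:
    """Scores for candidate pairs only; non-candidates never become edges."""
    rows = []
    known_mirnas = set(assoc.scores.columns)
    known_mrnas = set(assoc.scores.index)
    for mirna, mrna in candidates.sorted_pairs():
        if mirna not in known_mirnas:
            raise PLSError(f"unknown miRNA id {mirna!r}")
        if mrna not in known_mrnas:
            raise PLSError(f"unknown mRNA id {mrna!r}")
        rows.append((mirna, mrna, assoc.scores.at[mrna, mirna]))
    return pd.DataFrame(rows, columns=["mirna_id", "mrna_id", "score"])
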