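"""Minimal ROI-level GLM: design matrices, contrasts, and brain-behaviour tests.

Condition regressors are boxcars convolved with the canonical HRF; slow
scanner drift is absorbed by a discrete-cosine basis (128 s high-pass by
default) plus a constant.  Contrast inference is ordinary least squares
with t = c'b / sqrt(s2 c'(X'X)^-1 c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CATEGORIES, Paradigm, canonical_hrf

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "MedianSplitResult",
    "dct_drift_order",
    "build_design_matrix",
    "fit_glm",
    "group_contrast_correlation",
    "median_split_compare",
]


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with labelled columns."""

    matrix: pd.DataFrame
    tr: float

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(c for c in self.matrix.columns if c in CATEGORIES)

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


@dataclass
class GLMFit:
    betas: pd.Series
    residual_variance: float
    df: int
    contrast_values: dict[str, float]
    contrast_t: dict[str, float]
    residuals: np.ndarray


def dct_drift_order(n_scans: int, tr: float, cutoff: float = 128.0) -> int:
    """Number of DCT drift regressors for a given high-pass cutoff (seconds)."""
    if cutoff <= 0:
        return 0
    return max(int(math.floor(2.0 * n_scans * tr / cutoff)), 0)


def _dct_basis(n: int, order: int) -> np.ndarray:
    i = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * i + 1) / (2.0 * n))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def build_design_matrix(
    paradigm: Paradigm,
    hrf: np.ndarray | None = None,
    drift_order: int | None = None,
    highpass: float = 128.0,
) -> DesignMatrix:
    """HRF-convolved condition boxcars plus DCT drift columns and a constant.

    ``drift_order`` overrides the number of drift columns; by default it is
    derived from the *highpass* cutoff.  Conditions absent from the paradigm
    get no column.
    """
    if hrf is None:
        hrf = canonical_hrf(paradigm.tr)
    if drift_order is None:
        drift_order = dct_drift_order(paradigm.n_scans, paradigm.tr, highpass)
    if drift_order < 0:
        raise ValueError("drift_order must be >= 0")

    cols, labels = [], []
    present = paradigm.counts()
    for cat in CATEGORIES:
        if present.get(cat, 0) > 0:
            box = paradigm.boxcar(cat)
            cols.append(np.convolve(box, hrf)[: paradigm.n_scans])
            labels.append(cat)
    drift = _dct_basis(paradigm.n_scans, drift_order)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        labels.append(f"drift_{k + 1}")
    cols.append(np.ones(paradigm.n_scans))
    labels.append("constant")

    X = np.column_stack(cols)
    if np.linalg.cond(X) > 1e10:
        raise ValueError(
            "design matrix is ill-conditioned: a condition column is "
            "collinear with the drift/constant set"
        )
    return DesignMatrix(
        matrix=pd.DataFrame(X, columns=labels), tr=paradigm.tr
    )


def _collinear_columns(X: np.ndarray, labels) -> list[str]:
    """Columns whose removal restores full rank (best-effort diagnosis)."""
    rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            bad.append(labels[j])
    return bad


def _contrast_vector(contrast: dict[str, float], labels) -> np.ndarray:
    c = np.zeros(len(labels))
    for name, w in contrast.items():
        if name not in labels:
            raise KeyError(f"contrast names unknown regressor {name!r}")
        c[list(labels).index(name)] = w
    return c


def fit_glm(
    ts: np.ndarray | pd.Series,
    X: DesignMatrix,
    contrasts: dict[str, dict[str, float]] | None = None,
) -> GLMFit:
    """Ordinary least squares of one ROI series on a design matrix.

    ``contrasts`` maps names to weight dicts over regressor labels, e.g.
    ``{"care_gt_neutral": {"care": 1, "neutral": -1}}``.
    """
    y = np.asarray(ts, dtype=float).ravel()
    M = X.to_numpy()
    if len(y) != M.shape[0]:
        raise ValueError("series length must equal the design's row count")
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        bad = _collinear_columns(M, X.labels)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    df = len(y) - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    XtX_inv = np.linalg.inv(M.T @ M)
    beta = XtX_inv @ (M.T @ y)
    resid = y - M @ beta
    sigma2 = float(resid @ resid) / df

    cvals, ctvals = {}, {}
    for name, weights in (contrasts or {}).items():
        c = _contrast_vector(weights, X.labels)
        est = float(c @ beta)
        var = sigma2 * float(c @ XtX_inv @ c)
        cvals[name] = est
        ctvals[name] = est / math.sqrt(var) if var > 0 else 0.0
    return GLMFit(
        betas=pd.Series(beta, index=list(X.labels)),
        residual_variance=sigma2,
        df=df,
        contrast_values=cvals,
        contrast_t=ctvals,
        residuals=resid,
    )


def group_contrast_correlation(contrast_values, scores):
    """Pearson r, r^2 and the F-test p of regressing scores on contrast values."""
    x = np.asarray(contrast_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("contrast values and scores must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in contrast values or scores")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.rvalue**2), float(res.pvalue)


@dataclass
class MedianSplitResult:
    median: float
    high_mask: np.ndarray
    score_mean_high: float
    score_sd_high: float
    score_mean_low: float
    score_sd_low: float
    contrast_mean_high: float
    contrast_mean_low: float
    t: float
    p: float


def median_split_compare(scores, contrast_values) -> MedianSplitResult:
    """Welch t-test of contrast values between high/low median-split groups.

    Subjects scoring strictly above the median form the "high" group; ties
    at the median go to "low" (a deterministic rule).
    """
    scores = np.asarray(scores, dtype=float)
    contrast_values = np.asarray(contrast_values, dtype=float)
    if len(scores) != len(contrast_values):
        raise ValueError("scores and contrast values must have equal length")
    if np.all(scores == scores[0]):
        raise ValueError("all scores identical; median split undefined")
    med = float(np.median(scores))
    high = scores > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("need at least 2 subjects per split group")
    a, b = contrast_values[high], contrast_values[~high]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0  # degenerate: identical constant contrasts
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return MedianSplitResult(
        median=med,
        high_mask=high,
        score_mean_high=float(scores[high].mean()),
        score_sd_high=float(scores[high].std(ddof=1)),
        score_mean_low=float(scores[~high].mean()),
        score_sd_low=float(scores[~high].std(ddof=1)),
        contrast_mean_high=float(contrast_values[high].mean()),
        contrast_mean_low=float(contrast_values[~high].mean()),
        t=float(t),
        p=float(p),
    )
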