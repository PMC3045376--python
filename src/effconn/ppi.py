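"""Psychophysiological interaction (PPI) analysis at the ROI level.

A PPI regression asks whether the coupling between a seed region's
activity (the physiological variable) and a target series changes with the
task context (the psychological variable).  The regressor of interest is
their product; a significant interaction slope indicates task-modulated
connectivity.  Two constructions are provided: the classic product of the
observed (centered) seed with the condition vector, and a deconvolution
variant that forms the product at the neural scale before re-convolving
with the HRF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .glm import DesignMatrix
from .synthetic import Paradigm, canonical_hrf

__all__ = [
    "PPIRegressors",
    "PPIResult",
    "first_eigenvariate",
    "build_ppi_regressors",
    "fit_ppi",
    "group_ppi_test",
]


@dataclass
class PPIRegressors:
    physiological: np.ndarray
    psychological: np.ndarray
    interaction: np.ndarray
    mode: str
    contrast: tuple[str, str]

    def __post_init__(self):
        n = len(self.physiological)
        if len(self.psychological) != n or len(self.interaction) != n:
            raise ValueError("all three regressors must have identical length")


@dataclass
class PPIResult:
    beta: float
    t: float
    df: int
    p: float
    seed: str = ""
    target: str = ""
    contrast: str = ""


def first_eigenvariate(series_matrix) -> np.ndarray:
    """Representative series of an ROI: first left singular vector.

    Columns are member series (e.g. voxels of a sphere); the matrix is
    column-centered, the first left singular vector extracted, scaled to the
    standard deviation of the mean member series, and signed so that it
    correlates positively with that mean series.
    """
    M = np.asarray(series_matrix, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[1] < 1:
        raise ValueError("need at least one member column")
    Xc = M - M.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("zero-variance series matrix")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    u = U[:, 0] * s[0]
    mean_series = M.mean(axis=1)
    sd_mean = mean_series.std(ddof=1)
    sd_u = u.std(ddof=1)
    if sd_u > 0 and sd_mean > 0:
        u = u * (sd_mean / sd_u)
    mc = mean_series - mean_series.mean()
    if float(u @ mc) < 0:
        u = -u
    return u


def _conv_matrix(h: np.ndarray, n: int) -> np.ndarray:
    C = np.zeros((n, n))
    for k, hk in enumerate(h[:n]):
        C += hk * np.eye(n, k=-k)
    return C


def _gcv_ridge(C: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ridge deconvolution with the penalty chosen by generalized cross-validation."""
    n = len(y)
    U, s, Vt = np.linalg.svd(C)
    b = U.T @ y
    best_z, best_score = None, np.inf
    for lam in np.logspace(-6, 2, 25) * (s[0] ** 2):
        filt = s / (s**2 + lam)
        z = Vt.T @ (filt * b)
        trace_H = float(np.sum(s**2 / (s**2 + lam)))
        resid = y - C @ z
        denom = max(n - trace_H, 1e-6)
        score = n * float(resid @ resid) / denom**2
        if score < best_score:
            best_score, best_z = score, z
    return best_z


def build_ppi_regressors(
    seed: np.ndarray | pd.Series,
    paradigm: Paradigm,
    contrast: tuple[str, str],
    mode: str = "multiply",
    hrf: np.ndarray | None = None,
) -> PPIRegressors:
    """Construct the physiological, psychological, and interaction regressors.

    The psychological vector codes scans of ``contrast[0]`` as +1 and of
    ``contrast[1]`` as -1 (0 elsewhere), then mean-centers the coded scans.
    ``mode='multiply'`` multiplies the centered seed by this vector;
    ``mode='deconvolve'`` first deconvolves the seed to the neural scale by
    GCV-ridge least squares against the HRF convolution operator, multiplies
    there, and re-convolves.
    """
    if mode not in ("multiply", "deconvolve"):
        raise ValueError("mode must be 'multiply' or 'deconvolve'")
    cond_a, cond_b = contrast
    present = paradigm.counts()
    for c in (cond_a, cond_b):
        if present.get(c, 0) == 0:
            raise ValueError(f"contrast condition {c!r} not present in paradigm")
    y = np.asarray(seed, dtype=float).ravel()
    if len(y) != paradigm.n_scans:
        raise ValueError("seed length must equal the paradigm's n_scans")

    psych = paradigm.boxcar(cond_a) - paradigm.boxcar(cond_b)
    coded = psych != 0
    if not coded.any():
        raise ValueError("psychological vector codes no scans")
    psych = psych.copy()
    psych[coded] -= psych[coded].mean()

    physio = y - y.mean()
    if mode == "multiply":
        interaction = physio * psych
    else:
        if hrf is None:
            hrf = canonical_hrf(paradigm.tr)
        C = _conv_matrix(hrf, paradigm.n_scans)
        z = _gcv_ridge(C, physio)
        interaction = C @ (z * psych)
    return PPIRegressors(
        physiological=physio,
        psychological=psych,
        interaction=interaction,
        mode=mode,
        contrast=(cond_a, cond_b),
    )


def fit_ppi(
    target: np.ndarray | pd.Series,
    regs: PPIRegressors,
    confounds: DesignMatrix | np.ndarray | None = None,
    seed_label: str = "",
    target_label: str = "",
) -> PPIResult:
    """OLS of a target series on [physio, psych, interaction, confounds, 1].

    Reports the interaction term's slope and t statistic -- the test for
    task-dependent seed-target coupling.
    """
    y = np.asarray(target, dtype=float).ravel()
    cols = [regs.physiological, regs.psychological, regs.interaction]
    if confounds is not None:
        if isinstance(confounds, DesignMatrix):
            keep = [
                c for c in confounds.matrix.columns
                if c.startswith("drift_")
            ]
            extra = confounds.matrix[keep].to_numpy()
        else:
            extra = np.asarray(confounds, dtype=float)
            if extra.ndim == 1:
                extra = extra[:, None]
        cols.extend(extra.T)
    cols.append(np.ones(len(y)))
    X = np.column_stack(cols)
    if len(y) != X.shape[0]:
        raise ValueError("target length must match the regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear PPI regressors")
    df = len(y) - rank
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = math.sqrt(sigma2 * XtX_inv[2, 2]) if sigma2 > 0 else 0.0
    t = beta[2] / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df)
    return PPIResult(
        beta=float(beta[2]),
        t=float(t),
        df=int(df),
        p=float(p),
        seed=seed_label,
        target=target_label,
        contrast=f"{regs.contrast[0]}_vs_{regs.contrast[1]}",
    )


def group_ppi_test(betas_condition_a, betas_condition_b):
    """Paired t-test on per-subject interaction slopes across two conditions."""
    a = np.asarray(betas_condition_a, dtype=float)
    b = np.asarray(betas_condition_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 subjects")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0):
        if np.allclose(diff, 0):
            return 0.0, 1.0, len(a) - 1
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), len(a) - 1
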