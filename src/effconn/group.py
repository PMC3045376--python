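"""Group-level inference on path coefficients.

Covers the cross-condition pathwise comparisons (paired t-tests with
Bonferroni control), per-subject confirmatory fits of a fixed group
topology, and stepwise regression of per-subject path coefficients onto a
behaviour score (forward entry by partial F at p_in, backward removal at
p_out -- the classic stepwise convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sem import ConditionSeries, PathModel, fit_sem

__all__ = [
    "PathComparison",
    "StepwiseResult",
    "bonferroni_threshold",
    "count_shared_paths",
    "compare_paths",
    "confirmatory_fit_cohort",
    "stepwise_regress",
    "path_label",
]


def path_label(source: str, target: str) -> str:
    return f"{source}->{target}"


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance level alpha / n."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def count_shared_paths(models: dict[str, PathModel]):
    """Directed paths present in at least two condition models.

    Returns ``(count, sorted path list)``.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 condition models")
    tally: dict[tuple[str, str], int] = {}
    for model in models.values():
        for edge in set(model.edges):
            tally[edge] = tally.get(edge, 0) + 1
    shared = sorted(e for e, c in tally.items() if c >= 2)
    return len(shared), shared


@dataclass
class PathComparison:
    path: tuple[str, str]
    conditions: tuple[str, str]
    beta_a: float
    beta_b: float
    t: float
    p: float
    threshold: float
    significant: bool
    comparable: bool = True


def compare_paths(
    subject_fits_a: pd.DataFrame,
    subject_fits_b: pd.DataFrame,
    paths,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    conditions: tuple[str, str] = ("A", "B"),
) -> list[PathComparison]:
    """Paired t-tests comparing per-subject path coefficients across conditions.

    ``subject_fits_*`` are subjects x paths tables (columns labelled
    'source->target').  A path missing from either table is returned marked
    not-comparable rather than silently dropped.  The per-comparison
    threshold is alpha / n_comparisons.
    """
    if len(subject_fits_a) != len(subject_fits_b):
        raise ValueError("paired subjects required: tables differ in length")
    if len(subject_fits_a) < 3:
        raise ValueError("need at least 3 subjects")
    paths = list(paths)
    if n_comparisons is None:
        n_comparisons = len(paths)
    thr = bonferroni_threshold(alpha, n_comparisons)
    out = []
    for src, tgt in paths:
        label = path_label(src, tgt)
        if label not in subject_fits_a.columns or label not in subject_fits_b.columns:
            out.append(
                PathComparison(
                    path=(src, tgt),
                    conditions=conditions,
                    beta_a=float("nan"),
                    beta_b=float("nan"),
                    t=float("nan"),
                    p=float("nan"),
                    threshold=thr,
                    significant=False,
                    comparable=False,
                )
            )
            continue
        a = subject_fits_a[label].to_numpy(dtype=float)
        b = subject_fits_b[label].to_numpy(dtype=float)
        diff = a - b
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        out.append(
            PathComparison(
                path=(src, tgt),
                conditions=conditions,
                beta_a=float(a.mean()),
                beta_b=float(b.mean()),
                t=float(t),
                p=float(p),
                threshold=thr,
                significant=bool(p < thr),
            )
        )
    return out


def confirmatory_fit_cohort(
    cohort: dict[str, ConditionSeries],
    group_model: PathModel,
    restarts: int = 5,
    seed: int = 0,
):
    """Fit a fixed group topology to every subject's condition covariance.

    Returns ``(coefficients, diagnostics)``: a subjects x paths coefficient
    table containing only subjects whose fit converged, and a per-subject
    diagnostics table with convergence flags and reasons.  A subject whose
    covariance is singular or whose fit fails to converge is excluded from
    the coefficient table but retained in the diagnostics.
    """
    ss = np.random.SeedSequence(seed)
    labels = [path_label(s, t) for s, t in group_model.edges]
    rows, diag = {}, []
    for subject_id, cs in cohort.items():
        child = ss.spawn(1)[0]
        try:
            fit = fit_sem(
                cs.S, cs.n_samples, group_model, restarts=restarts, seed=child
            )
        except ValueError as exc:
            diag.append(
                {"subject": subject_id, "converged": False, "reason": str(exc)}
            )
            continue
        if fit.converged:
            rows[subject_id] = dict(
                zip(labels, fit.paths["beta"].to_numpy(), strict=True)
            )
            diag.append({"subject": subject_id, "converged": True, "reason": ""})
        else:
            diag.append(
                {"subject": subject_id, "converged": False, "reason": fit.message}
            )
    coefficients = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    diagnostics = pd.DataFrame(diag).set_index("subject")
    return coefficients, diagnostics


@dataclass
class StepwiseResult:
    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    r2_by_step: list[float] = field(default_factory=list)
    coefficients: pd.Series = None
    intercept: float = float("nan")

    @property
    def r2(self) -> float:
        return self.r2_by_step[-1] if self.r2_by_step else 0.0


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def stepwise_regress(
    coefficients: pd.DataFrame,
    scores,
    p_in: float = 0.05,
    p_out: float = 0.10,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward-backward stepwise regression of scores on path coefficients.

    At each step the candidate with the largest partial correlation (the
    largest increment F) enters if its partial F-test p-value is below
    *p_in*; any included predictor whose partial F p-value rises above
    *p_out* is removed.  Iterates to a fixed point.  An empty selection is
    a legitimate outcome, not an error.
    """
    y = np.asarray(scores, dtype=float)
    X_all = coefficients.to_numpy(dtype=float)
    names = list(coefficients.columns)
    n, m = X_all.shape
    if len(y) != n:
        raise ValueError("scores and coefficient table differ in length")
    if np.any(np.std(X_all, axis=0) == 0):
        bad = [names[j] for j in np.where(np.std(X_all, axis=0) == 0)[0]]
        raise ValueError(f"constant predictor columns: {bad}")
    if n <= m and m > 0 and n <= 3:
        raise ValueError("too few subjects for stepwise selection")

    def design(idx):
        return np.column_stack([X_all[:, idx], np.ones(n)]) if idx else np.ones((n, 1))

    result = StepwiseResult()
    included: list[int] = []
    tss = float(((y - y.mean()) ** 2).sum())
    for _ in range(max_steps):
        changed = False
        # forward entry
        rss_cur = _ols_rss(design(included), y)
        if tss <= 0 or rss_cur <= 1e-12 * tss:
            break  # perfect fit: partial F on round-off noise is meaningless
        best_j, best_F, best_p = None, -np.inf, 1.0
        for j in range(m):
            if j in included:
                continue
            trial = included + [j]
            k = len(trial)
            df2 = n - k - 1
            if df2 <= 0:
                continue
            rss_new = _ols_rss(design(trial), y)
            if rss_new >= rss_cur:
                continue
            F = (rss_cur - rss_new) / (rss_new / df2)
            if F > best_F:
                p = float(stats.f.sf(F, 1, df2))
                best_j, best_F, best_p = j, F, p
        if best_j is not None and best_p < p_in:
            included.append(best_j)
            rss_cur = _ols_rss(design(included), y)
            r2 = 1.0 - rss_cur / tss if tss > 0 else 0.0
            result.steps.append(
                {
                    "action": "enter",
                    "predictor": names[best_j],
                    "p": best_p,
                    "r2": r2,
                }
            )
            result.r2_by_step.append(r2)
            changed = True
        # backward removal
        while len(included) > 0:
            rss_full = _ols_rss(design(included), y)
            k = len(included)
            df2 = n - k - 1
            worst_i, worst_p = None, -1.0
            for i in included:
                rest = [j for j in included if j != i]
                rss_wo = _ols_rss(design(rest), y)
                F = (rss_wo - rss_full) / (rss_full / df2) if rss_full > 0 else np.inf
                p = float(stats.f.sf(F, 1, df2))
                if p > worst_p:
                    worst_i, worst_p = i, p
            if worst_p > p_out:
                included.remove(worst_i)
                rss_cur = _ols_rss(design(included), y)
                r2 = 1.0 - rss_cur / tss if tss > 0 else 0.0
                result.steps.append(
                    {
                        "action": "remove",
                        "predictor": names[worst_i],
                        "p": worst_p,
                        "r2": r2,
                    }
                )
                changed = True
            else:
                break
        if not changed:
            break

    result.selected = [names[j] for j in included]
    if included:
        X = design(included)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        result.coefficients = pd.Series(beta[:-1], index=result.selected)
        result.intercept = float(beta[-1])
    else:
        result.coefficients = pd.Series(dtype=float)
        result.intercept = float(y.mean())
    return result
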