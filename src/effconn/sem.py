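"""Maximum-likelihood path analysis (SEM) on ROI covariance matrices.

The structural model is the linear system x = B x + zeta with free directed
path coefficients B (zero diagonal) and free diagonal innovation variances
psi, implying the covariance

    Sigma(B, psi) = (I - B)^-1 diag(psi) (I - B)^-T.

Fitting minimises the maximum-likelihood discrepancy

    F_ML(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free parameters; chi^2 = (n - 1) F_ML.  Exploratory search
enumerates every admissible directed-edge subset, fits each, and ranks the
converged fits by a chosen index (AIC by default) -- the brute-force
model-space search used for effective-connectivity discovery.

Conventions follow the classic covariance-structure (Lisrel-style)
formulation: sample covariance with denominator n - 1, model AIC
chi^2 + 2q, and GFI/AGFI/PGFI as defined in `fit_indices`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .synthetic import Paradigm, ROITimeSeries

__all__ = [
    "ConditionSeries",
    "PathModel",
    "SEMFit",
    "SearchResult",
    "extract_condition_blocks",
    "model_implied_covariance",
    "ml_discrepancy",
    "fit_sem",
    "fit_indices",
    "enumerate_models",
    "exploratory_search",
]


# --------------------------------------------------------------------------
# Condition-block extraction
# --------------------------------------------------------------------------


@dataclass
class ConditionSeries:
    """Scans extracted from one condition's blocks, with their covariance."""

    condition: str
    samples: pd.DataFrame
    S: pd.DataFrame = None

    def __post_init__(self):
        if self.S is None:
            if len(self.samples) < self.samples.shape[1] + 1:
                raise ValueError("need at least (ROIs + 1) samples for a covariance")
            cov = np.cov(self.samples.to_numpy(), rowvar=False, ddof=1)
            self.S = pd.DataFrame(
                cov, index=self.samples.columns, columns=self.samples.columns
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def extract_condition_blocks(
    ts: ROITimeSeries,
    paradigm: Paradigm,
    condition: str,
    shift: float = 6.0,
    drop_head: int = 2,
    drop_tail: int = 1,
) -> ConditionSeries:
    """Extract the scans of one condition's blocks, delayed and trimmed.

    Each block's window is shifted by *shift* seconds to absorb the
    hemodynamic delay ([onset+shift, onset+duration+shift)); the first
    *drop_head* and last *drop_tail* scans of every window are dropped to
    suppress transition effects.  Surviving scans are concatenated and the
    sample covariance (denominator n-1) computed.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    blocks = paradigm.segments_of(condition)
    if not blocks:
        raise ValueError(f"condition {condition!r} not present in paradigm")
    t = np.arange(ts.n_scans) * ts.tr
    pieces = []
    for seg in blocks:
        lo, hi = seg.onset + shift, seg.onset + seg.duration + shift
        idx = np.where((t >= lo - 1e-9) & (t < hi - 1e-9))[0]
        kept = idx[drop_head : len(idx) - drop_tail] if drop_tail else idx[drop_head:]
        if len(kept) < 1:
            raise ValueError(
                f"block at onset {seg.onset} s yields no samples after trimming"
            )
        pieces.append(ts.data.iloc[kept])
    samples = pd.concat(pieces, axis=0, ignore_index=True)
    return ConditionSeries(condition=condition, samples=samples)


# --------------------------------------------------------------------------
# Model, implied covariance, discrepancy
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PathModel:
    """Directed path topology over named ROIs with free residual variances."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # (source, target)

    def __post_init__(self):
        known = set(self.nodes)
        seen = set()
        for src, tgt in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop {src!r} not allowed")
            if src not in known or tgt not in known:
                raise ValueError(f"edge ({src!r}, {tgt!r}) references unknown node")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge ({src!r}, {tgt!r})")
            seen.add((src, tgt))

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def q(self) -> int:
        """Free parameters: one per edge plus one residual variance per node."""
        return len(self.edges) + len(self.nodes)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.q

    def is_recursive(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return nx.is_directed_acyclic_graph(g)


def model_implied_covariance(B: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Sigma = (I - B)^-1 diag(psi) (I - B)^-T."""
    B = np.asarray(B, dtype=float)
    psi = np.asarray(psi, dtype=float)
    p = B.shape[0]
    if np.any(psi <= 0):
        raise ValueError("psi must be strictly positive")
    A = np.eye(p) - B
    if np.linalg.svd(A, compute_uv=False)[-1] <= 1e-12:
        raise ValueError("I - B is singular")
    iA = np.linalg.inv(A)
    Sigma = (iA * psi) @ iA.T
    return (Sigma + Sigma.T) / 2.0


def _chol_logdet(M: np.ndarray, name: str):
    try:
        c = linalg.cholesky(M, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc
    return c, 2.0 * float(np.sum(np.log(np.diag(c))))


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p  (>= 0, 0 iff S == Sigma)."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if S.shape != Sigma.shape or S.shape != (p, p):
        raise ValueError("S and Sigma must be square matrices of equal order")
    cS, logdet_S = _chol_logdet(S, "S")
    cSig, logdet_Sig = _chol_logdet(Sigma, "Sigma")
    trace = float(np.trace(linalg.cho_solve((cSig, True), S)))
    f = logdet_Sig + trace - logdet_S - p
    return max(f, 0.0) if f > -1e-10 else f


# --------------------------------------------------------------------------
# ML fitting
# --------------------------------------------------------------------------


@dataclass
class SEMFit:
    """One model fit to one covariance: estimates, SEs, and fit-index panel."""

    model: PathModel
    B: pd.DataFrame
    psi: pd.Series
    paths: pd.DataFrame  # source, target, beta, se, t
    psi_table: pd.DataFrame  # node, psi, se, t
    fml: float
    chi2: float
    df: int
    n: int
    indices: dict[str, float]
    converged: bool
    grad_norm: float
    spectral_radius: float
    recursive: bool
    message: str = ""

    @property
    def Sigma_hat(self) -> np.ndarray:
        return model_implied_covariance(self.B.to_numpy(), self.psi.to_numpy())


def _as_matrix(S, nodes):
    if isinstance(S, pd.DataFrame):
        missing = [r for r in nodes if r not in S.index]
        if missing:
            raise ValueError(f"covariance is missing nodes {missing}")
        return S.loc[list(nodes), list(nodes)].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    if S.shape != (len(nodes), len(nodes)):
        raise ValueError("covariance shape does not match the node list")
    return S


def _objective_factory(S: np.ndarray, tgt_idx: np.ndarray, src_idx: np.ndarray):
    p = S.shape[0]
    nE = len(tgt_idx)
    eye = np.eye(p)
    _, logdet_S = np.linalg.slogdet(S)

    def fun_grad(theta: np.ndarray):
        # Sigma = iA diag(psi) iA^T is PD whenever psi > 0 and A is
        # invertible, so Sigma^-1 = A^T diag(1/psi) A and
        # ln|Sigma| = sum(ln psi) - 2 ln|det A| need no factorization.
        B = np.zeros((p, p))
        B[tgt_idx, src_idx] = theta[:nE]
        logpsi = theta[nE:]
        if np.max(np.abs(logpsi)) > 40 or np.max(np.abs(theta[:nE]), initial=0) > 1e6:
            return 1e12, np.zeros_like(theta)
        psi = np.exp(logpsi)
        A = eye - B
        detA = np.linalg.det(A)
        if abs(detA) < 1e-12 or not np.isfinite(detA):
            return 1e12, np.zeros_like(theta)
        iA = np.linalg.inv(A)
        Sigma = (iA * psi) @ iA.T
        Sigma_inv = (A.T / psi) @ A
        logdet_Sig = float(np.sum(logpsi)) - 2.0 * np.log(abs(detA))
        f = logdet_Sig + float(np.einsum("ij,ji->", Sigma_inv, S)) - logdet_S - p
        if not np.isfinite(f):
            return 1e12, np.zeros_like(theta)
        # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
        G = Sigma_inv - Sigma_inv @ S @ Sigma_inv
        gradB = 2.0 * (iA.T @ G @ Sigma)  # dF/dB_ij at [i, j]
        grad_edges = gradB[tgt_idx, src_idx]
        M = iA.T @ G @ iA
        grad_logpsi = np.diag(M) * psi
        return f, np.concatenate([grad_edges, grad_logpsi])

    return fun_grad


def _numeric_hessian(fun_grad, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        d = np.zeros(k)
        d[i] = step
        _, gp = fun_grad(theta + d)
        _, gm = fun_grad(theta - d)
        H[i] = (gp - gm) / (2 * step)
    return (H + H.T) / 2.0


def fit_sem(
    S,
    n: int,
    model: PathModel,
    restarts: int = 10,
    seed: int = 0,
    gtol: float = 1e-8,
    compute_se: bool = True,
) -> SEMFit:
    """Fit one path topology to a covariance matrix by multi-start ML.

    Residual variances are kept positive through a log parameterisation.
    After quasi-Newton minimisation the best candidate is polished with
    Newton steps on the numerically evaluated Hessian.  Standard errors come
    from the observed information of the fit function scaled by (n - 1):
    acov = 2 / (n - 1) * H^-1.  A fit that misses the gradient tolerance or
    whose Hessian is not positive definite is returned with
    ``converged=False`` (never an exception) -- the analogue of a
    covariance-structure program failing to converge on a stable solution.
    """
    nodes = model.nodes
    p = len(nodes)
    S = _as_matrix(S, nodes)
    if n <= p + 1:
        raise ValueError("n must exceed p + 1")
    if model.q > p * (p + 1) // 2:
        raise ValueError(
            f"model has q={model.q} free parameters but only "
            f"{p * (p + 1) // 2} covariance moments (under-identified)"
        )
    _chol_logdet(S, "S")

    node_idx = {r: i for i, r in enumerate(nodes)}
    tgt_idx = np.array([node_idx[t] for _, t in model.edges], dtype=int)
    src_idx = np.array([node_idx[s] for s, _ in model.edges], dtype=int)
    nE = len(model.edges)
    fun_grad = _objective_factory(S, tgt_idx, src_idx)

    rng = np.random.default_rng(seed)
    log_diag = np.log(np.clip(np.diag(S), 1e-8, None))
    starts = [np.concatenate([np.zeros(nE), log_diag])]
    for _ in range(max(restarts - 1, 0)):
        starts.append(
            np.concatenate(
                [rng.uniform(-0.8, 0.8, size=nE), log_diag + rng.normal(0, 0.3, p)]
            )
        )

    best_theta, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            fun_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-15, "gtol": 1e-10},
        )
        if res.fun < best_f:
            best_f, best_theta = res.fun, res.x

    theta = best_theta
    f, g = fun_grad(theta)
    H = None
    # Newton polish towards the gradient tolerance; under-identified models
    # (singular or indefinite information) fall out of this loop quickly and
    # are flagged as non-converged below.
    for _ in range(10):
        if np.max(np.abs(g)) < gtol:
            break
        H = _numeric_hessian(fun_grad, theta)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(delta)) or np.max(np.abs(delta)) > 1e4:
            break
        step = 1.0
        improved = False
        for _ in range(8):
            f_new, g_new = fun_grad(theta - step * delta)
            if f_new <= f + 1e-12:
                theta, f, g = theta - step * delta, f_new, g_new
                improved = True
                break
            step /= 2.0
        if not improved:
            break
        H = None

    grad_norm = float(np.max(np.abs(g)))
    if H is None:
        H = _numeric_hessian(fun_grad, theta)
    try:
        hess_chol = linalg.cholesky(H, lower=True)
        hess_pd = True
    except linalg.LinAlgError:
        hess_chol, hess_pd = None, False
    converged = bool(grad_norm < gtol and hess_pd)
    message = ""
    if not converged:
        reasons = []
        if grad_norm >= gtol:
            reasons.append(f"gradient norm {grad_norm:.2e} above tolerance {gtol:.0e}")
        if not hess_pd:
            reasons.append("observed information not positive definite")
        message = "; ".join(reasons)

    beta = theta[:nE]
    psi = np.exp(theta[nE:])
    B = np.zeros((p, p))
    B[tgt_idx, src_idx] = beta

    se = np.full(nE + p, np.nan)
    if hess_pd and compute_se:
        acov = 2.0 / (n - 1) * linalg.cho_solve((hess_chol, True), np.eye(nE + p))
        dvar = np.diag(acov)
        if np.all(dvar > 0):
            se = np.sqrt(dvar)
    se_beta = se[:nE]
    se_psi = se[nE:] * psi  # delta method from the log scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t_beta = beta / se_beta
        t_psi = psi / se_psi

    B_df = pd.DataFrame(B, index=list(nodes), columns=list(nodes))
    psi_s = pd.Series(psi, index=list(nodes), name="psi")
    paths = pd.DataFrame(
        {
            "source": [s for s, _ in model.edges],
            "target": [t for _, t in model.edges],
            "beta": beta,
            "se": se_beta,
            "t": t_beta,
        }
    )
    psi_table = pd.DataFrame(
        {"node": list(nodes), "psi": psi, "se": se_psi, "t": t_psi}
    )
    chi2 = (n - 1) * f
    eigvals = np.linalg.eigvals(B)
    fit = SEMFit(
        model=model,
        B=B_df,
        psi=psi_s,
        paths=paths,
        psi_table=psi_table,
        fml=float(f),
        chi2=float(chi2),
        df=model.df,
        n=int(n),
        indices={},
        converged=converged,
        grad_norm=grad_norm,
        spectral_radius=float(np.max(np.abs(eigvals))) if p else 0.0,
        recursive=model.is_recursive(),
        message=message,
    )
    fit.indices = fit_indices(fit, S)
    return fit


def fit_indices(fit: SEMFit, S=None) -> dict[str, float]:
    """Fit-index panel: chi2, RMSEA, AIC, SRMR, GFI, AGFI, PGFI, min |t|.

    chi2 = (n-1) F_ML; RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)));
    AIC = chi2 + 2q (model AIC); GFI = 1 - tr[(Sigma^-1 S - I)^2] /
    tr[(Sigma^-1 S)^2]; AGFI = 1 - [p(p+1) / (2 df)] (1 - GFI);
    PGFI = [2 df / (p(p+1))] GFI; SRMR is the RMS of the standardized
    residuals of S - Sigma over unique elements.  Indices whose formula
    divides by df are reported as NaN when df = 0.
    """
    if S is None:
        raise ValueError("the observed covariance S is required")
    S = _as_matrix(S, fit.model.nodes)
    p = fit.model.p
    q = fit.model.q
    df = fit.df
    n = fit.n
    chi2 = fit.chi2
    Sigma = fit.Sigma_hat

    W = np.linalg.solve(Sigma, S)
    gfi = 1.0 - np.trace((W - np.eye(p)) @ (W - np.eye(p))) / np.trace(W @ W)
    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
        pgfi = (2.0 * df / (p * (p + 1))) * gfi
    else:
        rmsea = agfi = pgfi = float("nan")
    d = np.sqrt(np.diag(S))
    R = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(R[iu] ** 2)))
    t_paths = fit.paths["t"].to_numpy()
    if len(t_paths) and np.any(np.isfinite(t_paths)):
        min_t = float(np.nanmin(np.abs(t_paths)))
    else:
        min_t = float("nan")
    return {
        "chi2": float(chi2),
        "fml": float(fit.fml),
        "rmsea": rmsea,
        "aic": float(chi2 + 2 * q),
        "srmr": srmr,
        "gfi": float(gfi),
        "agfi": float(agfi),
        "pgfi": float(pgfi),
        "min_t": min_t,
    }


# --------------------------------------------------------------------------
# Exhaustive enumeration and exploratory search
# --------------------------------------------------------------------------


def enumerate_models(
    nodes,
    max_edges: int | None = None,
    require_df_nonneg: bool = True,
):
    """Yield every directed-edge-subset model, smallest first.

    Order is deterministic: edge-count ascending, then lexicographic in the
    (source, target) pairs under the given node order.
    """
    nodes = tuple(nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    p = len(nodes)
    all_edges = [(s, t) for s in nodes for t in nodes if s != t]
    limit = len(all_edges)
    if require_df_nonneg:
        limit = min(limit, p * (p + 1) // 2 - p)
    if max_edges is not None:
        limit = min(limit, max_edges)
    for k in range(limit + 1):
        for subset in itertools.combinations(all_edges, k):
            yield PathModel(nodes=nodes, edges=subset)


@dataclass
class SearchResult:
    """Ranked outcome of an exhaustive model search."""

    ranked: list[SEMFit]
    failures: list[SEMFit] = field(default_factory=list)
    rank_by: str = "aic"

    @property
    def best(self) -> SEMFit:
        return self.ranked[0]


_RANKABLE = ("aic", "rmsea", "chi2", "fml", "srmr")


def exploratory_search(
    S,
    n: int,
    nodes,
    max_edges: int | None = None,
    require_df_nonneg: bool = True,
    rank_by: str = "aic",
    seed: int = 0,
    restarts: int = 3,
    gtol: float = 1e-8,
) -> SearchResult:
    """Fit every enumerated model and rank the converged fits.

    Non-converged fits are excluded from the ranking but retained (with the
    reason) in ``failures``.  Ties in the ranking criterion break by RMSEA,
    then by fewer edges, then by enumeration order.
    """
    if rank_by not in _RANKABLE:
        raise ValueError(f"rank_by must be one of {_RANKABLE}")
    nodes = tuple(nodes)
    ss = np.random.SeedSequence(seed)
    fits, failures = [], []
    for i, model in enumerate(enumerate_models(nodes, max_edges, require_df_nonneg)):
        fit = fit_sem(
            S, n, model, restarts=restarts, seed=ss.spawn(1)[0], gtol=gtol
        )
        (fits if fit.converged else failures).append((i, fit))
    if not fits:
        detail = "; ".join(
            f"{f.model.edges}: {f.message}" for _, f in failures[:10]
        )
        raise RuntimeError(f"no model converged in the search ({detail})")

    def key(item):
        # Criterion values are quantized so that fits that are numerically
        # equivalent (e.g. covariance-equivalent topologies, whose optima
        # differ only by optimizer round-off) fall through to the stated
        # deterministic tie-breaks: RMSEA, then fewer edges, then
        # enumeration order.
        i, fit = item
        val = fit.indices[rank_by]
        rmsea = fit.indices["rmsea"]
        return (
            round(val, 4) if np.isfinite(val) else np.inf,
            round(rmsea, 6) if np.isfinite(rmsea) else np.inf,
            len(fit.model.edges),
            i,
        )

    ranked = [fit for _, fit in sorted(fits, key=key)]
    return SearchResult(
        ranked=ranked, failures=[f for _, f in failures], rank_by=rank_by
    )
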