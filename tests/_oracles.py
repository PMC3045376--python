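"""Independent brute-force oracles shared by the SEM test modules."""

import itertools

import numpy as np
from scipy import optimize


def _oracle_search_ranking(S, n, nodes):
    """Independent brute-force search: own enumeration, optimizer and AIC.

    Fits each edge subset by direct minimisation of the ML discrepancy with
    numerically differentiated gradients and bounded residual variances.
    """
    S = np.asarray(S, dtype=float)
    p = len(nodes)
    sign, logdet_S = np.linalg.slogdet(S)

    def discrepancy(theta, pairs):
        B = np.zeros((p, p))
        for k, (i, j) in enumerate(pairs):
            B[j, i] = theta[k]
        psi = theta[len(pairs):]
        A = np.eye(p) - B
        try:
            Sigma = np.linalg.solve(A, np.diag(psi)) @ np.linalg.inv(A).T
        except np.linalg.LinAlgError:
            return 1e9
        vals = np.linalg.eigvalsh((Sigma + Sigma.T) / 2)
        if np.min(vals) <= 1e-10:
            return 1e9
        return (
            np.sum(np.log(vals))
            + np.trace(np.linalg.solve(Sigma, S))
            - logdet_S
            - p
        )

    idx = list(range(p))
    all_pairs = [(i, j) for i in idx for j in idx if i != j]
    results = []
    order = 0
    for k in range(p * (p + 1) // 2 - p + 1):
        for pairs in itertools.combinations(all_pairs, k):
            x0 = np.concatenate([np.zeros(k), np.diag(S)])
            best = None
            for attempt in range(3):
                if attempt:
                    rng = np.random.default_rng(1000 * order + attempt)
                    x0 = np.concatenate(
                        [rng.uniform(-0.5, 0.5, k), np.diag(S) * rng.uniform(0.5, 2, p)]
                    )
                res = optimize.minimize(
                    discrepancy,
                    x0,
                    args=(pairs,),
                    method="L-BFGS-B",
                    bounds=[(None, None)] * k + [(1e-6, None)] * p,
                    options={"maxiter": 1000, "ftol": 1e-15},
                )
                if best is None or res.fun < best:
                    best = res.fun
            q = k + p
            aic = (n - 1) * best + 2 * q
            edge_set = frozenset(
                (nodes[i], nodes[j]) for i, j in pairs
            )
            results.append((aic, k, order, edge_set))
            order += 1
    results.sort(key=lambda r: (round(r[0], 3), r[1], r[2]))
    return results
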