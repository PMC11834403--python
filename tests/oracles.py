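"""Independent reference implementations used only to check the package.

These are deliberately written with different algorithms from the
production code: the graphical lasso is solved by projected-gradient
ascent on the dual (box-constrained log-det maximization) instead of
coordinate descent, permutation tests are brute-force enumerations, and
rank transforms are recomputed from first principles.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm, rankdata, spearmanr


def pgd_glasso(S: np.ndarray, lam: float, iters: int = 4000) -> np.ndarray:
    """Graphical lasso via projected gradient ascent on the dual:
    maximize log det(S + U) over |U_ij| <= lam off-diagonal, U_ii = 0.
    Returns the primal precision Theta = (S + U)^{-1}."""
    p = S.shape[0]
    U = np.zeros((p, p))
    t = 0.1
    for _ in range(iters):
        theta = np.linalg.inv(S + U)
        step = t
        while True:
            U_new = np.clip(U + step * theta, -lam, lam)
            np.fill_diagonal(U_new, 0.0)
            try:
                np.linalg.cholesky(S + U_new)
                break
            except np.linalg.LinAlgError:
                step /= 2
        U = U_new
    return np.linalg.inv(S + U)


def brute_force_mantel_p(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """Exact one-sided Mantel p by enumerating all n! joint permutations."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    obs = spearmanr(d1[iu], d2[iu]).statistic
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = spearmanr(d1[iu], d2[np.ix_(perm, perm)][iu]).statistic
        count += r >= obs - 1e-12
        total += 1
    return obs, count / total


def brute_force_anosim(d: np.ndarray, groups) -> tuple[float, float]:
    """Exact ANOSIM by enumerating all label permutations."""
    groups = np.asarray(groups)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    M = n * (n - 1) // 2

    def R(g):
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    obs = R(groups)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        count += R(groups[list(perm)]) >= obs - 1e-12
        total += 1
    return obs, count / total


def rank_quantile_npn(x: np.ndarray) -> np.ndarray:
    """First-principles nonparanormal marginal: average-tie ranks,
    truncated ECDF, normal quantile, unit sample variance."""
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sx = x[order]
    while i < n:
        j = i
        while j + 1 < n and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    delta = 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))
    z = norm.ppf(np.clip(ranks / n, delta, 1 - delta))
    return z / z.std(ddof=1)


def hat_matrix_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """RDA R^2 via the explicit hat matrix H = Xc (Xc'Xc)^{-1} Xc'."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
    return float(np.trace(Yc.T @ H @ Yc) / np.trace(Yc.T @ Yc))


def edge_f1(estimated: set, truth: set) -> float:
    tp = len(estimated & truth)
    if not estimated or not truth or tp == 0:
        return 0.0
    prec, rec = tp / len(estimated), tp / len(truth)
    return 2 * prec * rec / (prec + rec)
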