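"""Redundancy analysis with forward selection of environmental predictors.

RDA asks what fraction of the multivariate community variance (here, CLR
abundances) lies in the column space of the predictors: the community
matrix is projected onto the environmental matrix and the fitted values are
eigen-decomposed.  Variable selection proceeds forward, adding at each step
the candidate that most increases the adjusted R^2; a candidate is accepted
only while (a) its Bonferroni-adjusted permutation p-value stays below
alpha and (b) the cumulative adjusted R^2 has not exceeded that of the
global model with all candidates (the double stopping rule, which guards
against the optimistic bias of stepwise selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RdaModel:
    selected: list[str]
    r2: float
    adj_r2: float
    total_variance: float
    constrained_variance: float
    eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: np.ndarray | None = None
    pvalues: dict[str, float] = field(default_factory=dict)
    pvalues_adjusted: dict[str, float] = field(default_factory=dict)
    selection_trace: list[dict] = field(default_factory=list)
    global_adj_r2: float | None = None

    @property
    def empty(self) -> bool:
        return not self.selected


def _as_matrix(M) -> tuple[np.ndarray, list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(M.columns)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M, [f"x{i}" for i in range(M.shape[1])]


def _fit_stats(Yc: np.ndarray, X: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Explained sum of squares, residual SS and fitted values of the
    projection of (centered) Y onto the column space of (centered) X."""
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    Yhat = Q @ (Q.T @ Yc)
    ess = float((Yhat ** 2).sum())
    rss = float(((Yc - Yhat) ** 2).sum())
    return ess, rss, Yhat


def adjusted_r2(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda_fit(Y, X) -> RdaModel:
    """Fit an RDA of community matrix Y (samples x features, centered
    internally) constrained by predictor matrix X.

    R^2 = trace(Yhat' Yhat) / trace(Yc' Yc); the adjusted value applies the
    usual (n-1)/(n-m-1) small-sample correction with m predictors.
    Constrained axes come from the SVD of the fitted matrix.
    """
    Ym, _ = _as_matrix(Y)
    Xm, xnames = _as_matrix(X)
    if Ym.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X must have the same number of samples")
    n = Ym.shape[0]
    Xc = Xm - Xm.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < Xm.shape[1]:
        raise ValueError(
            "predictor matrix is rank deficient; remove collinear variables"
        )
    Yc = Ym - Ym.mean(axis=0)
    total = float((Yc ** 2).sum())
    if total == 0:
        raise ValueError("community matrix has no variance")
    ess, rss, Yhat = _fit_stats(Yc, Xm)
    r2 = ess / total
    m = Xm.shape[1]
    u, s, _ = np.linalg.svd(Yhat, full_matrices=False)
    eig = (s ** 2) / (n - 1)
    eig = eig[eig > 1e-12 * max(eig.max(), 1.0)]
    ru, rs, _ = np.linalg.svd(Yc - Yhat, full_matrices=False)
    reig = (rs ** 2) / (n - 1)
    reig = reig[reig > 1e-12 * max(reig.max() if len(reig) else 1.0, 1.0)]
    return RdaModel(
        selected=xnames,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, m),
        total_variance=total / (n - 1),
        constrained_variance=ess / (n - 1),
        eigenvalues=eig,
        unconstrained_eigenvalues=reig,
        site_scores=u[:, : len(eig)] * s[: len(eig)],
    )


def _partial_f(Yc, X_red, x_new) -> float:
    """Pseudo-F for adding one predictor to the reduced model."""
    n = Yc.shape[0]
    if X_red is None or X_red.shape[1] == 0:
        ess_red = 0.0
        X_full = x_new[:, None] if x_new.ndim == 1 else x_new
        m_full = 1
    else:
        ess_red, _, _ = _fit_stats(Yc, X_red)
        X_full = np.column_stack([X_red, x_new])
        m_full = X_full.shape[1]
    ess_full, rss_full, _ = _fit_stats(Yc, X_full)
    df_res = n - m_full - 1
    if df_res <= 0 or rss_full <= 0:
        return np.inf
    return (ess_full - ess_red) / (rss_full / df_res)


def forward_select(
    Y,
    X_candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> RdaModel:
    """Forward selection of RDA predictors with permutation tests.

    At each step the candidate giving the largest adjusted R^2 is proposed;
    its marginal significance is assessed by permuting the residuals of the
    reduced model (the fitted reduced part is held fixed) and recomputing
    the partial pseudo-F, with the add-one estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  The Bonferroni factor is
    the number of candidates still in play at that step.  Selection stops
    when the adjusted p exceeds alpha or when the cumulative adjusted R^2
    would exceed that of the global (all-candidate) model.
    """
    Ym, _ = _as_matrix(Y)
    Xall, names = _as_matrix(X_candidates)
    if len(names) < 1:
        raise ValueError("need at least one candidate")
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0)
    total = float((Yc ** 2).sum())
    rng = np.random.default_rng(seed)

    global_model = rda_fit(Ym, Xall)
    selected: list[str] = []
    pvals: dict[str, float] = {}
    padj: dict[str, float] = {}
    trace: list[dict] = []
    remaining = list(names)

    prev_adj = 0.0
    while remaining:
        X_red = (Xall[:, [names.index(v) for v in selected]]
                 if selected else None)
        best, best_adj = None, -np.inf
        for cand in remaining:
            cols = selected + [cand]
            X_try = Xall[:, [names.index(v) for v in cols]]
            ess, _, _ = _fit_stats(Yc, X_try)
            a = adjusted_r2(ess / total, n, len(cols))
            if a > best_adj:
                best, best_adj = cand, a

        # scope guard: the proposed model must improve on the current one
        # and stay within the global model's adjusted R^2, otherwise the
        # term would only be chasing noise — stop without testing it
        if best_adj <= prev_adj or best_adj > global_model.adj_r2:
            trace.append({
                "step": len(selected) + 1, "variable": best,
                "adj_r2": best_adj, "p": None, "p_adj": None,
                "n_candidates": len(remaining), "stopped_by": "r2_scope",
            })
            break

        # permutation test for the proposed term under the reduced model
        x_new = Xall[:, names.index(best)]
        if X_red is None:
            fitted_red = np.zeros_like(Yc)
            resid_red = Yc
        else:
            _, _, fitted_red = _fit_stats(Yc, X_red)
            resid_red = Yc - fitted_red
        f_obs = _partial_f(Yc, X_red, x_new)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Y_perm = fitted_red + resid_red[perm]
            count += _partial_f(Y_perm, X_red, x_new) >= f_obs - 1e-12
        p = (1 + count) / (1 + n_perm)
        p_adj = min(1.0, p * len(remaining))
        trace.append({
            "step": len(selected) + 1, "variable": best, "adj_r2": best_adj,
            "p": p, "p_adj": p_adj, "n_candidates": len(remaining),
        })
        if p_adj >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
        prev_adj = best_adj
        pvals[best] = p
        padj[best] = p_adj

    if not selected:
        model = RdaModel(
            selected=[], r2=0.0, adj_r2=0.0, total_variance=total / (n - 1),
            constrained_variance=0.0, eigenvalues=np.array([]),
            unconstrained_eigenvalues=np.array([]),
        )
    else:
        model = rda_fit(Ym, pd.DataFrame(
            Xall[:, [names.index(v) for v in selected]], columns=selected))
    model.pvalues = pvals
    model.pvalues_adjusted = padj
    model.selection_trace = trace
    model.global_adj_r2 = global_model.adj_r2
    return model
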