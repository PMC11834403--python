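"""Sparse Gaussian graphical-model estimation with stability selection.

The precision matrix Theta of a multivariate Gaussian encodes conditional
independence: Theta_ij = 0 iff features i and j are independent given all
others.  The graphical lasso maximizes the L1-penalized log-likelihood

    log det Theta - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|

(diagonal unpenalized) over positive-definite Theta, yielding a sparse
edge set whose entries give partial correlations
rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).  The penalty is chosen by
StARS: solve a 30-value lambda path on many random subsamples, measure
per-edge selection instability, and keep the densest graph whose
(monotonized) average instability stays below a threshold beta.

The solver is block coordinate descent over lasso subproblems (one column
of the covariance estimate at a time), compiled with numba; KKT residuals
are exposed so optimality is checkable independently of the solve path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

_EDGE_EPS = 1e-10


@dataclass(frozen=True)
class LambdaPath:
    """Log-spaced decreasing regularization path."""

    values: np.ndarray
    lambda_max: float
    ratio: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if len(v) < 1 or (v <= 0).any() or (np.diff(v) >= 0).any():
            raise ValueError("path must be strictly decreasing and positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def build_path(
    X: pd.DataFrame, n_lambda: int = 30, ratio: float = 0.1
) -> tuple[np.ndarray, LambdaPath]:
    """Empirical correlation matrix and a log-spaced lambda path from
    lambda_max = max off-diagonal |correlation| down to ratio*lambda_max.

    At lambda_max the solved graph has no edges (the penalty dominates
    every off-diagonal correlation)."""
    if len(X) < 4:
        raise ValueError("need at least 4 samples")
    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    const = [c for c, s in zip(X.columns, sd) if s == 0]
    if const:
        raise ValueError(f"constant features: {const}")
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1); ratio=1 is a degenerate path")
    S = np.corrcoef(vals, rowvar=False)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max == 0:
        raise ValueError("all features uncorrelated; lambda path undefined")
    path = np.geomspace(lam_max, ratio * lam_max, n_lambda)
    return S, LambdaPath(path, lam_max, ratio)


@njit(cache=True)
def _glasso_bcd(S, lam, W, B, tol_w, max_iter):  # pragma: no cover - jitted
    p = S.shape[0]
    inner_tol = tol_w * 0.01
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            for _sweep in range(200):
                delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    acc = 0.0
                    for m in range(p):
                        if m != j and m != k:
                            acc += W[k, m] * B[m, j]
                    r = S[k, j] - acc
                    old = B[k, j]
                    if r > lam:
                        new = (r - lam) / W[k, k]
                    elif r < -lam:
                        new = (r + lam) / W[k, k]
                    else:
                        new = 0.0
                    B[k, j] = new
                    d = abs(new - old)
                    if d > delta:
                        delta = d
                if delta < inner_tol:
                    break
            for k in range(p):
                if k != j:
                    acc = 0.0
                    for m in range(p):
                        if m != j:
                            acc += W[k, m] * B[m, j]
                    d = abs(acc - W[k, j])
                    if d > max_delta:
                        max_delta = d
                    W[k, j] = acc
                    W[j, k] = acc
        if max_delta < tol_w:
            break
    # recover Theta from the final W and regression coefficients
    theta = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        for k in range(p):
            if k != j:
                acc += W[j, k] * B[k, j]
        tjj = 1.0 / (W[j, j] - acc)
        theta[j, j] = tjj
        for k in range(p):
            if k != j:
                theta[k, j] = -B[k, j] * tjj
    # symmetrize (column solves agree at convergence up to tolerance)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (theta[i, j] + theta[j, i])
            if theta[i, j] == 0.0 or theta[j, i] == 0.0:
                v = 0.0
            theta[i, j] = v
            theta[j, i] = v
    return theta


@dataclass
class PrecisionGraph:
    """Estimated precision matrix with its edge set."""

    theta: pd.DataFrame
    lam: float
    feature_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.theta.columns)

    def adjacency(self) -> np.ndarray:
        th = self.theta.to_numpy()
        adj = np.abs(th) > _EDGE_EPS
        np.fill_diagonal(adj, False)
        return adj

    def edge_set(self) -> set[frozenset]:
        feats = self.features
        adj = self.adjacency()
        iu = np.triu_indices(len(feats), k=1)
        return {
            frozenset((feats[i], feats[j]))
            for i, j in zip(*iu) if adj[i, j]
        }

    def partial_correlations(self) -> pd.DataFrame:
        """Edge list with partial correlations -Theta_ij/sqrt(ii*jj)."""
        th = self.theta.to_numpy()
        feats = self.features
        d = np.sqrt(np.diag(th))
        rows = []
        iu = np.triu_indices(len(feats), k=1)
        adj = self.adjacency()
        for i, j in zip(*iu):
            if adj[i, j]:
                rows.append({
                    "feature_a": feats[i],
                    "feature_b": feats[j],
                    "partial_corr": -th[i, j] / (d[i] * d[j]),
                    "kind_pair": "-".join(sorted((
                        self.feature_kinds.get(feats[i], "asv"),
                        self.feature_kinds.get(feats[j], "asv"),
                    ))),
                })
        return pd.DataFrame(
            rows, columns=["feature_a", "feature_b", "partial_corr", "kind_pair"]
        )

    def n_edges(self) -> int:
        return int(self.adjacency().sum() // 2)

    def edge_partition(self) -> dict[str, int]:
        """Edge counts split into ASV-ASV vs ASV-environment pairs."""
        pc = self.partial_correlations()
        return {
            "asv-asv": int((pc["kind_pair"] == "asv-asv").sum()),
            "asv-env": int((pc["kind_pair"] == "asv-env").sum()),
            "env-env": int((pc["kind_pair"] == "env-env").sum()),
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(selected_lambda=float(self.lam))
        for f in self.features:
            g.add_node(f, kind=self.feature_kinds.get(f, "asv"))
        for _, row in self.partial_correlations().iterrows():
            g.add_edge(row["feature_a"], row["feature_b"],
                       partial_corr=float(row["partial_corr"]),
                       kind_pair=row["kind_pair"])
        return g


def glasso_objective(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Penalized negative log-likelihood
    -log det Theta + tr(S Theta) + lam * sum_{i != j}|Theta_ij|."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    pen = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(-logdet + np.trace(S @ theta) + lam * pen)


def kkt_residual(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Max violation of the stationarity conditions: W = Theta^{-1} must
    satisfy W_ij - S_ij = lam*sign(Theta_ij) on edges, |W_ij - S_ij| <= lam
    off edges, and W_ii = S_ii (unpenalized diagonal)."""
    W = np.linalg.inv(theta)
    diff = W - S
    res = float(np.max(np.abs(np.diag(diff))))
    p = S.shape[0]
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if abs(theta[i, j]) > _EDGE_EPS:
                res = max(res, abs(diff[i, j] - lam * np.sign(theta[i, j])))
            else:
                res = max(res, abs(diff[i, j]) - lam)
    return res


def _solve_raw(S, lam, tol, max_iter, warm=None):
    """Run the coordinate-descent kernel; returns (theta, (W, B))."""
    p = S.shape[0]
    if warm is not None:
        W, B = warm[0].copy(), warm[1].copy()
    else:
        W, B = S.copy(), np.zeros((p, p))
    tol_w = tol * max(np.abs(S - np.diag(np.diag(S))).mean(), 1e-12)
    theta = _glasso_bcd(S, lam, W, B, tol_w, max_iter)
    return theta, (W, B)


def glasso_solve(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 200,
    features=None,
    feature_kinds=None,
) -> PrecisionGraph:
    """Solve the graphical lasso at one penalty by block coordinate descent.

    Raises if the KKT residual of the result exceeds tolerance after
    ``max_iter`` outer cycles.  At lambda = 0 the solution is the
    unpenalized maximum-likelihood precision, S^{-1}.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be square symmetric")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    features = list(features) if features is not None else [f"f{i}" for i in range(p)]

    if lam == 0.0:
        theta = np.linalg.inv(S)
    else:
        theta, _ = _solve_raw(S, lam, tol, max_iter)
        res = kkt_residual(S, theta, lam)
        if res > max(10 * tol, 1e-4):
            raise RuntimeError(
                f"glasso did not reach tolerance: KKT residual {res:.2e}"
            )
    return PrecisionGraph(
        theta=pd.DataFrame(theta, index=features, columns=features),
        lam=float(lam),
        feature_kinds=dict(feature_kinds or {}),
    )


def solve_path(S, path: LambdaPath, features=None, tol=1e-5, max_iter=200):
    """Solve the whole path (decreasing lambda) with warm starts; returns
    the list of boolean adjacency matrices."""
    S = np.asarray(S, dtype=float)
    adjs = []
    warm = None
    for lam in path.values:
        theta, warm = _solve_raw(S, lam, tol, max_iter, warm=warm)
        adj = np.abs(theta) > _EDGE_EPS
        np.fill_diagonal(adj, False)
        adjs.append(adj)
    return adjs


@dataclass
class StabilityPath:
    """Per-lambda edge-selection frequencies and instabilities."""

    path: LambdaPath
    selection_freq: np.ndarray  # (n_lambda, p, p) upper-triangular freq
    instability: np.ndarray  # D(lambda)
    monotone_instability: np.ndarray
    n_subsamples: int
    subsample_size: int
    beta: float
    selected_lambda: float
    selected_index: int


def default_subsample_size(n: int) -> int:
    """StARS convention: b = floor(10 sqrt(n)), capped below n."""
    return min(int(np.floor(10.0 * np.sqrt(n))), n - 1)


def stars_select(
    X: pd.DataFrame,
    path: LambdaPath | None = None,
    rep: int = 50,
    beta: float = 0.05,
    b: int | None = None,
    seed: int = 0,
    n_lambda: int = 30,
    ratio: float = 0.1,
    feature_kinds=None,
    tol: float = 1e-5,
) -> tuple[StabilityPath, PrecisionGraph]:
    """Stability Approach to Regularization Selection.

    Draw ``rep`` subsamples of size ``b`` without replacement, solve the
    lambda path on each, and compute per-edge selection frequencies
    theta-hat and the average instability D(lambda) = mean of
    2*theta-hat*(1-theta-hat) over feature pairs.  D is monotonized from
    the sparse end (running maximum toward smaller lambda) and the smallest
    lambda with monotonized D <= beta — the densest acceptably stable graph
    — is refit on the full data.
    """
    n, p = X.shape
    if rep < 2:
        raise ValueError("rep must be >= 2")
    S_full, full_path = build_path(X, n_lambda=n_lambda, ratio=ratio)
    if path is None:
        path = full_path
    b = b if b is not None else default_subsample_size(n)
    if not 1 < b < n:
        raise ValueError("subsample size b must satisfy 1 < b < n")
    rng = np.random.default_rng(seed)
    feats = list(X.columns)
    vals = X.to_numpy(dtype=float)

    counts = np.zeros((len(path), p, p))
    for _ in range(rep):
        idx = rng.choice(n, size=b, replace=False)
        sub = vals[idx]
        if (sub.std(axis=0) == 0).any():
            raise ValueError("constant feature within a subsample")
        S_sub = np.corrcoef(sub, rowvar=False)
        for k, adj in enumerate(solve_path(S_sub, path, features=feats, tol=tol)):
            counts[k] += adj

    freq = counts / rep
    xi = 2.0 * freq * (1.0 - freq)
    iu = np.triu_indices(p, k=1)
    D = np.array([xi[k][iu].mean() for k in range(len(path))])
    D_mono = np.maximum.accumulate(D)  # nondecreasing toward small lambda

    ok = np.where(D_mono <= beta)[0]
    if len(ok) == 0:
        warnings.warn(
            f"no lambda reaches instability <= {beta}; "
            "falling back to the sparsest graph (lambda_max)"
        )
        sel = 0
    else:
        sel = int(ok[-1])  # smallest lambda still acceptably stable
    lam_sel = float(path.values[sel])
    graph = glasso_solve(S_full, lam_sel, tol=tol, features=feats,
                         feature_kinds=feature_kinds)
    stability = StabilityPath(
        path=path, selection_freq=freq, instability=D,
        monotone_instability=D_mono, n_subsamples=rep, subsample_size=b,
        beta=beta, selected_lambda=lam_sel, selected_index=sel,
    )
    return stability, graph


@dataclass
class MergedEdges:
    """Edges detected in both depth networks, with both partial
    correlations, plus each network's ASV/environment edge partition."""

    shared: pd.DataFrame  # feature_a, feature_b, partial_corr_a, partial_corr_b
    partition_a: dict[str, int]
    partition_b: dict[str, int]


def extract_and_merge(netA: PrecisionGraph, netB: PrecisionGraph) -> MergedEdges:
    """Intersect two networks' edge sets on shared feature ids."""
    pa = {frozenset((r["feature_a"], r["feature_b"])): r["partial_corr"]
          for _, r in netA.partial_correlations().iterrows()}
    pb = {frozenset((r["feature_a"], r["feature_b"])): r["partial_corr"]
          for _, r in netB.partial_correlations().iterrows()}
    rows = []
    for pair in sorted(pa.keys() & pb.keys(), key=sorted):
        a, b = sorted(pair)
        rows.append({"feature_a": a, "feature_b": b,
                     "partial_corr_a": pa[pair], "partial_corr_b": pb[pair]})
    return MergedEdges(
        shared=pd.DataFrame(
            rows, columns=["feature_a", "feature_b",
                           "partial_corr_a", "partial_corr_b"]),
        partition_a=netA.edge_partition(),
        partition_b=netB.edge_partition(),
    )
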