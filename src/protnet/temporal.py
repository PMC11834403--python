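"""Temporal community-similarity analyses.

Bray-Curtis dissimilarity between sample pairs, binned by the number of
months separating the samples (days / 30.4), summarizes seasonal cyclicity
and long-term drift: in a strongly seasonal community, samples 12 months
apart are more similar than samples 6 months apart.  Mantel tests
(Spearman) assess whether time between samples predicts dissimilarity,
ANOSIM compares groups (e.g. surface vs deep chlorophyll maximum), and a
simple regression of similarity on pairwise distance along the first
principal component of the environmental table links community turnover to
environmental change.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .containers import EnvTable

#: average month length in days used to convert day lags to month lags
DAYS_PER_MONTH = 30.4


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with sample ids."""

    data: np.ndarray
    ids: list[str]
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def similarity(self) -> np.ndarray:
        """1 - distance (meaningful for metrics bounded in [0, 1])."""
        return 1.0 - self.data


def bray_curtis(abundance: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between every pair of samples:
    BC(i, k) = sum_j |x_ij - x_kj| / sum_j (x_ij + x_kj)."""
    x = abundance.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = abundance.index[x.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, list(abundance.index), "braycurtis")


def month_lag(days: float) -> float:
    """Day separation converted to months via the 30.4-day average month."""
    return abs(days) / DAYS_PER_MONTH


@dataclass
class LagSimilarityProfile:
    """Mean +/- SE similarity per integer month-lag bin."""

    table: pd.DataFrame  # columns: lag_months, mean_sim, se, n_pairs
    n_pairs_total: int
    n_pairs_excluded: int = 0


def lag_profile(dist: DistanceMatrix, dates) -> LagSimilarityProfile:
    """Bin unordered sample pairs by months apart and average similarity.

    Lags are binned to the nearest integer month (round half up).  Pairs
    zero days apart (duplicate dates) carry no temporal information and are
    excluded.
    """
    dates = pd.to_datetime(pd.Series(dates, index=dist.ids)
                           if not isinstance(dates, pd.Series) else dates)
    dates = dates.reindex(dist.ids)
    if dates.isna().any():
        raise ValueError("dates missing for some samples")
    day = dates.to_numpy(dtype="datetime64[D]").astype(float)
    iu = np.triu_indices(dist.n, k=1)
    ddays = np.abs(day[iu[0]] - day[iu[1]])
    sim = dist.similarity()[iu]
    keep = ddays > 0
    lags = ddays[keep] / DAYS_PER_MONTH
    bins = np.floor(lags + 0.5).astype(int)  # round half up
    sim = sim[keep]
    rows = []
    for b in np.unique(bins):
        vals = sim[bins == b]
        se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append({"lag_months": int(b), "mean_sim": vals.mean(),
                     "se": se, "n_pairs": len(vals)})
    return LagSimilarityProfile(
        table=pd.DataFrame(rows),
        n_pairs_total=len(ddays),
        n_pairs_excluded=int((~keep).sum()),
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str = "greater"


def _spearman_ranks(u_ranks: np.ndarray, v: np.ndarray) -> float:
    rv = rankdata(v)
    return float(np.corrcoef(u_ranks, rv)[0, 1])


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test with Spearman correlation of the off-diagonal distances.

    The second matrix's sample order is permuted jointly on rows and
    columns.  With ``exact=True`` all n! permutations are enumerated
    (n <= 8) and the p-value is the exact fraction of permutations with a
    statistic at least as extreme as observed (the identity included);
    otherwise the add-one permutation estimator
    p = (1 + #extreme) / (1 + n_perm) is used.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share sample ids and order")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1, v2 = d1.data[iu], d2.data[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("Mantel statistic undefined for constant distances")
    r1 = rankdata(v1)
    obs = _spearman_ranks(r1, v2)

    def extreme(r: float) -> bool:
        if alternative == "greater":
            return r >= obs - 1e-12
        if alternative == "two-sided":
            return abs(r) >= abs(obs) - 1e-12
        raise ValueError(f"unknown alternative {alternative!r}")

    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            d2p = d2.data[np.ix_(perm, perm)][iu]
            count += extreme(_spearman_ranks(r1, d2p))
            total += 1
        return MantelResult(obs, count / total, total, None, alternative)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d2p = d2.data[np.ix_(perm, perm)][iu]
        count += extreme(_spearman_ranks(r1, d2p))
    return MantelResult(obs, (1 + count) / (1 + n_perm), n_perm, seed, alternative)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int
    seed: int | None


def _anosim_R(rank_cond: np.ndarray, within: np.ndarray, M: int) -> float:
    return float((rank_cond[~within].mean() - rank_cond[within].mean()) / (M / 2.0))


def anosim(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities: R = (mean between-group rank - mean
    within-group rank) / (M/2) with M = n(n-1)/2, tested by permuting
    group labels."""
    groups = np.asarray(pd.Series(groups).reindex(dist.ids)
                        if isinstance(groups, (pd.Series, dict)) else groups)
    if len(groups) != dist.n:
        raise ValueError("group labels do not match samples")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    n = dist.n
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist.data[iu])
    M = n * (n - 1) // 2
    codes = np.searchsorted(labels, groups)
    obs = _anosim_R(ranks, codes[iu[0]] == codes[iu[1]], M)

    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            c = codes[list(perm)]
            count += _anosim_R(ranks, c[iu[0]] == c[iu[1]], M) >= obs - 1e-12
            total += 1
        return AnosimResult(obs, count / total, total, None)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        c = rng.permutation(codes)
        count += _anosim_R(ranks, c[iu[0]] == c[iu[1]], M) >= obs - 1e-12
    return AnosimResult(obs, (1 + count) / (1 + n_perm), n_perm, seed)


@dataclass
class Pc1RegressionResult:
    slope: float
    intercept: float
    p: float
    r2: float
    pc1_variance_ratio: float


def pc1_distance_regression(
    env: EnvTable, sim: DistanceMatrix
) -> Pc1RegressionResult:
    """Regress Bray-Curtis similarity on pairwise distance along PC1 of the
    standardized environmental table.

    A negative slope means communities are less similar when environmental
    conditions differ more.  PC1's sign is fixed by making its
    largest-magnitude loading positive (pairwise distances are unaffected).
    """
    if env.values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 environmental variables")
    if list(env.values.index) != list(sim.ids):
        raise ValueError("env table and distance matrix must share samples")
    x = env.values.to_numpy(dtype=float)
    pca = PCA(n_components=min(x.shape))
    scores = pca.fit_transform(x)
    load = pca.components_[0]
    sign = np.sign(load[np.argmax(np.abs(load))]) or 1.0
    pc1 = sign * scores[:, 0]
    iu = np.triu_indices(len(pc1), k=1)
    dpc1 = np.abs(pc1[iu[0]] - pc1[iu[1]])
    simv = sim.similarity()[iu]
    X = sm.add_constant(dpc1)
    fit = sm.OLS(simv, X).fit()
    return Pc1RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p=float(fit.pvalues[1]),
        r2=float(fit.rsquared),
        pc1_variance_ratio=float(pca.explained_variance_ratio_[0]),
    )
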