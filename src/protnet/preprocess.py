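"""Input parsing, prevalence filtering, CLR normalization and
environmental-table preparation.

ASV relative abundances are compositional: reads per sample are a fixed-size
draw, so only ratios carry information.  The centered log-ratio (CLR)
transform, ln(x_j / g(x)) with g the geometric sample mean, maps each
composition to unconstrained real space where covariance-based methods are
meaningful.  Zeros must be replaced first; the default is a unit pseudocount
on counts (for relative-abundance inputs, half the smallest nonzero value),
with multiplicative replacement available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import multi_replace
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, SimpleImputer
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import LinearRegression

from .containers import AsvTable, EnvTable, TaxonomyTable


def read_tables(
    counts_path,
    metadata_path,
    taxonomy_path,
    env_path=None,
) -> tuple[AsvTable, TaxonomyTable, EnvTable | None]:
    """Read and cross-validate the TSV inputs.

    Samples are aligned across tables by sample id; every ASV in the count
    table must have a taxonomy row, and every sample must appear in the
    metadata, otherwise a hard error lists the offenders.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "date", "depth"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    meta = meta.set_index("sample_id")
    missing = [s for s in counts.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    dates = pd.to_datetime(meta["date"], errors="coerce").reindex(counts.index)
    bad_dates = dates.index[dates.isna()].tolist()
    if bad_dates:
        raise ValueError(f"unparseable dates for samples: {bad_dates}")

    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    if not {"asv_id", "lineage"}.issubset(tax.columns):
        raise ValueError("taxonomy must have columns asv_id, lineage")
    lineages = {
        row["asv_id"]: [t.strip() for t in str(row["lineage"]).split(";")]
        for _, row in tax.iterrows()
    }
    missing_tax = [a for a in counts.columns if a not in lineages]
    if missing_tax:
        raise ValueError(f"ASVs absent from taxonomy: {missing_tax}")

    table = AsvTable(counts, dates, meta["depth"].reindex(counts.index))
    taxonomy = TaxonomyTable({a: lineages[a] for a in counts.columns})

    env = None
    if env_path is not None:
        ev = pd.read_csv(env_path, sep="\t", index_col=0)
        ev.index = ev.index.astype(str)
        absent = [s for s in counts.index if s not in ev.index]
        if absent:
            raise ValueError(f"samples absent from env table: {absent}")
        env = EnvTable(ev.loc[counts.index].astype(float))
    return table, taxonomy, env


def prevalence_filter(
    table: AsvTable, threshold: float = 0.20, verbose: bool = False
) -> AsvTable:
    """Keep ASVs that are non-zero in at least ``threshold`` of the samples.

    The bound is inclusive ("at least"): an ASV present in exactly 20% of
    samples is retained at the default threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frac = (table.counts.to_numpy() > 0).mean(axis=0)
    keep = frac >= threshold
    if not keep.any():
        raise ValueError("prevalence filter removed every ASV")
    kept = [a for a, k in zip(table.asv_ids, keep) if k]
    if verbose:
        print(f"prevalence_filter: kept {len(kept)} of {len(keep)} ASVs")
    return table.subset_asvs(kept)


@dataclass(frozen=True)
class ZeroPolicy:
    """How to remove zeros before taking log-ratios.

    ``pseudocount``: add c to every entry (c=None means 1 for count-like
    tables, half the smallest nonzero value for relative-abundance tables).
    ``multiplicative_replacement``: replace zeros with a small value and
    rescale nonzeros to preserve row sums.
    """

    method: str = "pseudocount"
    c: float | None = None

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.method == "pseudocount":
            c = self.c
            if c is None:
                if (x > 0).all():
                    return x  # nothing to replace; keeps exact scale invariance
                nz = x[x > 0]
                looks_relative = np.allclose(x.sum(axis=1), 1.0, atol=1e-6)
                c = nz.min() / 2.0 if looks_relative else 1.0
            return x + c
        if self.method == "multiplicative_replacement":
            rows = x / x.sum(axis=1, keepdims=True)
            return multi_replace(rows)
        raise ValueError(f"unknown zero policy {self.method!r}")


def clr_transform(
    table: AsvTable | pd.DataFrame, zero_policy: ZeroPolicy | None = None
) -> pd.DataFrame:
    """Centered log-ratio transform, row-wise: clr(x)_j = ln(x_j / g(x)).

    Every output row sums to zero; the transform is invariant to per-sample
    scaling (sequencing depth).
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    zero_rows = counts.index[(x.sum(axis=1) == 0)].tolist()
    if zero_rows:
        raise ValueError(f"all-zero samples (geometric mean undefined): {zero_rows}")
    zero_policy = zero_policy or ZeroPolicy()
    pos = zero_policy.apply(x)
    if (pos <= 0).any():
        raise ValueError("zero policy left non-positive entries")
    logx = np.log(pos)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


_IMPUTERS = {"iterative_trees", "iterative_linear", "mean"}


def prepare_env(
    env: EnvTable, impute_method: str = "iterative_trees", seed: int = 0
) -> EnvTable:
    """Impute missing covariate values, then standardize each variable to
    mean 0 and variance 1.

    The default imputer is iterative chained imputation with an
    extremely-randomized-trees regressor (same family as random-forest
    imputation, deterministic under the seed); ``iterative_linear`` and
    plain ``mean`` imputation are available.
    """
    if impute_method not in _IMPUTERS:
        raise ValueError(f"impute_method must be one of {sorted(_IMPUTERS)}")
    df = env.values
    all_missing = df.columns[df.isna().all()].tolist()
    if all_missing:
        raise ValueError(f"variables with no observed values: {all_missing}")
    few = df.columns[df.notna().sum() < 2].tolist()
    if few:
        raise ValueError(f"variables with fewer than 2 observed values: {few}")

    if df.isna().any().any():
        if impute_method == "mean":
            imp = SimpleImputer(strategy="mean")
        elif impute_method == "iterative_linear":
            imp = IterativeImputer(
                estimator=LinearRegression(), max_iter=25, tol=1e-8,
                random_state=seed, sample_posterior=False,
            )
        else:
            imp = IterativeImputer(
                estimator=ExtraTreesRegressor(n_estimators=50, random_state=seed),
                max_iter=10, random_state=seed,
            )
        filled = imp.fit_transform(df.to_numpy())
    else:
        filled = df.to_numpy(dtype=float).copy()

    const = df.columns[filled.std(axis=0, ddof=1) == 0].tolist()
    if const:
        raise ValueError(f"constant variables cannot be standardized: {const}")
    z = (filled - filled.mean(axis=0)) / filled.std(axis=0, ddof=1)
    return EnvTable(pd.DataFrame(z, index=df.index, columns=df.columns),
                    standardized=True)
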