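"""Seasonal/long-term detrending and rank-based Gaussianization.

Co-occurrence estimated from seasonal time series is dominated by shared
seasonality: any two taxa with summer maxima correlate whether or not they
interact.  Each feature (CLR abundance or environmental variable) is
therefore residualized against an additive model with a cyclic smooth of
day-of-year (annual period) plus a smooth long-term trend, and the
residuals are passed on to network estimation.

The residuals are then Gaussianized marginally with the truncated
empirical-CDF nonparanormal transform, so that the Gaussian graphical
model downstream is estimating the copula precision structure rather than
relying on normal margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.gam.api import CyclicCubicSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic import DAYS_PER_YEAR


@dataclass(frozen=True)
class SplineConfig:
    """Spline settings for the additive detrending model.

    ``doy_df`` basis functions for the cyclic day-of-year smooth (penalized;
    period one year), ``trend_df`` for the unpenalized long-term B-spline
    trend, ``alpha`` the penalty weight on the cyclic term; ``gcv=True``
    picks ``alpha`` per feature by generalized cross-validation instead.
    """

    doy_df: int = 6
    trend_df: int = 5
    alpha: float = 1.0
    gcv: bool = False


@dataclass
class DetrendedMatrix:
    """GAM residuals plus per-feature fit summaries.

    Downstream stages (the nonparanormal transform, network estimation)
    require this type so the CLR -> detrend -> Gaussianize order cannot be
    silently skipped or reordered.
    """

    values: pd.DataFrame
    summary: pd.DataFrame  # deviance_explained, fallback flag per feature
    dates: pd.Series
    config: SplineConfig = field(default_factory=SplineConfig)


def _trend_basis(t: np.ndarray, df: int) -> np.ndarray:
    """Unpenalized cubic B-spline basis (plus implicit intercept) for the
    long-term trend."""
    from scipy.interpolate import BSpline

    t0, t1 = t.min(), t.max()
    n_inner = max(df - 3, 0)
    inner = np.linspace(t0, t1, n_inner + 2)[1:-1]
    knots = np.concatenate([[t0] * 4, inner, [t1] * 4])
    design = BSpline.design_matrix(t, knots, 3).toarray()
    return design[:, 1:]  # drop one column: intercept is supplied separately


def _harmonic_fallback(y, doy, t):
    """Linear harmonic regression (annual sin/cos pair + linear trend)."""
    X = np.column_stack([
        np.ones_like(t),
        np.sin(2 * np.pi * doy / DAYS_PER_YEAR),
        np.cos(2 * np.pi * doy / DAYS_PER_YEAR),
        (t - t.mean()) / max(np.ptp(t), 1.0),
    ])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def gam_detrend(
    X: pd.DataFrame, dates, spline_config: SplineConfig | None = None
) -> DetrendedMatrix:
    """Residualize each feature against season (cyclic day-of-year smooth)
    and long-term trend (low-df B-spline), Gaussian identity link.

    Features whose additive fit fails fall back to linear harmonic
    regression with a warning.  Requires at least 12 samples spanning more
    than one year, otherwise the annual cycle is not identifiable.
    """
    cfg = spline_config or SplineConfig()
    dates = pd.to_datetime(pd.Series(dates, index=X.index)
                           if not isinstance(dates, pd.Series) else dates)
    dates = dates.reindex(X.index)
    if dates.isna().any():
        raise ValueError("dates missing for some samples")
    day = dates.to_numpy(dtype="datetime64[D]").astype(float)
    t = day - day.min()
    if len(X) < 12 or np.ptp(t) <= DAYS_PER_YEAR:
        raise ValueError(
            "detrending needs >= 12 samples spanning more than one year"
        )
    doy = (dates.dt.dayofyear - 1).to_numpy(float)

    cyclic = CyclicCubicSplines(pd.DataFrame({"doy": doy}), df=[cfg.doy_df])
    exog = np.column_stack([np.ones_like(t), _trend_basis(t, cfg.trend_df)])

    resid = np.empty_like(X.to_numpy(dtype=float))
    rows = []
    for k, col in enumerate(X.columns):
        y = X[col].to_numpy(dtype=float)
        tss = ((y - y.mean()) ** 2).sum()
        if tss == 0:
            resid[:, k] = 0.0
            rows.append({"feature": col, "deviance_explained": 0.0,
                         "fallback": False})
            continue
        try:
            model = GLMGam(y, exog=exog, smoother=cyclic, alpha=[cfg.alpha])
            if cfg.gcv:
                alpha_opt = model.select_penweight()[0]
                model = GLMGam(y, exog=exog, smoother=cyclic, alpha=alpha_opt)
            res = model.fit()
            r = np.asarray(res.resid_response)
            if not np.isfinite(r).all():
                raise ValueError("non-finite residuals")
            fallback = False
        except (np.linalg.LinAlgError, PerfectSeparationError, ValueError) as e:
            warnings.warn(f"GAM fit failed for {col!r} ({e}); "
                          "using harmonic-regression fallback")
            r = _harmonic_fallback(y, doy, t)
            fallback = True
        resid[:, k] = r
        rows.append({
            "feature": col,
            "deviance_explained": 1.0 - (r ** 2).sum() / tss,
            "fallback": fallback,
        })
    return DetrendedMatrix(
        values=pd.DataFrame(resid, index=X.index, columns=X.columns),
        summary=pd.DataFrame(rows).set_index("feature"),
        dates=dates,
        config=cfg,
    )


def npn_delta(n: int) -> float:
    """Truncation level of the nonparanormal empirical CDF,
    1 / (4 n^{1/4} sqrt(pi log n))."""
    return 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))


def npn_marginal(x: np.ndarray) -> np.ndarray:
    """Truncated-ECDF Gaussianization of one feature: average-tie ranks ->
    r/n clamped to [delta, 1-delta] -> standard normal quantile -> rescaled
    to unit sample variance."""
    from scipy.stats import rankdata

    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("constant feature: ranks degenerate")
    u = rankdata(x) / n
    d = npn_delta(n)
    z = norm.ppf(np.clip(u, d, 1.0 - d))
    return z / z.std(ddof=1)


def nonparanormal(X: DetrendedMatrix) -> pd.DataFrame:
    """Feature-wise nonparanormal transform of detrended residuals.

    The transform depends on the data only through ranks, so it is exactly
    invariant under strictly increasing marginal transformations.
    """
    if not isinstance(X, DetrendedMatrix):
        raise TypeError(
            "nonparanormal expects a DetrendedMatrix (run gam_detrend first; "
            "use npn_marginal directly for raw columns)"
        )
    df = X.values
    if len(df) < 4:
        raise ValueError("nonparanormal needs at least 4 samples")
    out = {col: npn_marginal(df[col].to_numpy(dtype=float)) for col in df.columns}
    return pd.DataFrame(out, index=df.index)
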