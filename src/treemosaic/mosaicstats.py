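"""Chromosome-size regressions on tree-likeness (PCVE) and the
edge-count-versus-slope correlation.

The regression is a conjugate Bayesian normal linear model on standardized
variables (both response and predictor scaled to mean 0, SD 1), so the slope
is dimensionless and comparable across numbers of migration edges.  The
posterior is analytic (normal-inverse-gamma), no sampler involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RegressionResult
from .quartet import pearson_with_ci


class StatsError(ValueError):
    pass


def _standardize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    centered = v - v.mean()
    if sd == 0:
        return centered, True
    return centered / sd, False


def conjugate_regression(
    x: np.ndarray,
    y: np.ndarray,
    prior_scale: float = 1.0,
    a0: float = 2.0,
    b0: float = 1.0,
) -> RegressionResult:
    """Bayesian simple regression with a normal-inverse-gamma prior.

    Both variables are standardized; coefficients have prior
    N(0, sigma^2 * prior_scale^2) (so the slope prior is ~N(0,1) on the
    standardized scale, where sigma is near 1) and sigma^2 ~
    Inv-Gamma(a0, b0).  Returns the posterior slope mean, 95% equal-tail
    probability interval, the posterior probability that the slope is
    negative, and the ordinary least-squares R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise StatsError("need at least 3 observations")
    xs, x_flat = _standardize(x)
    ys, y_flat = _standardize(y)
    if x_flat:
        raise StatsError("zero variance in predictor: regression undefined")
    design = np.column_stack([np.ones(n), xs])
    v0_inv = np.eye(2) / prior_scale**2
    vn_inv = v0_inv + design.T @ design
    vn = np.linalg.inv(vn_inv)
    mn = vn @ (design.T @ ys)
    an = a0 + n / 2.0
    bn = b0 + 0.5 * float(ys @ ys - mn @ vn_inv @ mn)
    scale = np.sqrt(bn / an * vn[1, 1])
    dof = 2.0 * an
    beta = float(mn[1])
    tdist = stats.t(df=dof, loc=beta, scale=scale)
    lo, hi = tdist.ppf(0.025), tdist.ppf(0.975)
    prob_neg = float(tdist.cdf(0.0))
    # least-squares R^2 on the standardized data
    if y_flat:
        r2 = 0.0
    else:
        slope_ols = float(xs @ ys / (xs @ xs))
        resid = ys - slope_ols * xs
        r2 = float(1.0 - (resid @ resid) / (ys @ ys))
    return RegressionResult(
        beta=beta,
        etpi=(float(lo), float(hi)),
        prob_negative=prob_neg,
        r2=r2,
        n=n,
        flagged=y_flat,
    )


def pcve_size_regression(
    pcve: pd.Series | np.ndarray, sizes: pd.Series | np.ndarray
) -> RegressionResult:
    """Standardized Bayesian regression of per-chromosome PCVE on chromosome
    size in base pairs.  The caller excludes the Z chromosome when the
    autosome-only relationship is wanted."""
    if isinstance(pcve, pd.Series) and isinstance(sizes, pd.Series):
        common = [c for c in pcve.index if c in sizes.index]
        pcve = pcve.loc[common].to_numpy()
        sizes = sizes.loc[common].to_numpy()
    return conjugate_regression(np.asarray(sizes, float), np.asarray(pcve, float))


def slope_edge_correlation(slopes: dict[int, float] | pd.Series):
    """Pearson correlation between the number of migration edges m and the
    standardized size-PCVE slope at m, with Fisher-z CI and t-test P."""
    if isinstance(slopes, dict):
        slopes = pd.Series(slopes).sort_index()
    m = slopes.index.to_numpy(dtype=float)
    s = slopes.to_numpy(dtype=float)
    if len(m) < 3:
        raise StatsError("need slopes for at least 3 edge counts")
    return pearson_with_ci(m, s)
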