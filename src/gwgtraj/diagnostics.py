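"""Model-adequacy and reliability statistics.

Normalized quantile residuals with their four-moment summary and the
Filliben probability-plot correlation, worm-plot (detrended Q-Q)
coordinates, the generalised R-squared, and the two-way mixed-effects
intraclass correlation (absolute agreement and consistency forms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import distributions as dist
from .engine import FittedModel

__all__ = [
    "ResidualSummary",
    "IccResult",
    "quantile_residuals",
    "residual_summary",
    "worm_plot_data",
    "generalized_r2",
    "icc_two_way",
    "order_statistic_medians",
]

CDF_CLIP = 1e-12


@dataclass
class ResidualSummary:
    """Four standardized moments plus the Filliben correlation.

    Kurtosis is raw (normal reference 3), not excess; moments use
    divisor n so standard-normal residuals give variance ~1.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    filliben: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class IccResult:
    icc_absolute: float
    icc_consistency: float
    ci_absolute: tuple[float, float]
    ci_consistency: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "icc_absolute": self.icc_absolute,
            "icc_consistency": self.icc_consistency,
            "ci_absolute": list(self.ci_absolute),
            "ci_consistency": list(self.ci_consistency),
        }


def quantile_residuals(
    fit: FittedModel, data: Optional[pd.DataFrame] = None
) -> np.ndarray:
    """Normalized quantile residuals: Phi^{-1} of the fitted CDF at each
    observation. Standard normal when the model is correctly specified.

    With ``data`` omitted the training observations and their fitted
    parameters are used; otherwise parameters are predicted for the new
    table (which must carry ``gwg_kg``).
    """
    if data is None:
        y = fit.y_model_scale
        p = fit.param_set()
    else:
        y = data["gwg_kg"].to_numpy(dtype=float)
        if fit.shift is not None:
            y = fit.shift.to_model_scale(y)
        p = fit.predict_params(data)
    u = dist.family_cdf(fit.family, y, p)
    clipped = (u < CDF_CLIP) | (u > 1.0 - CDF_CLIP)
    if np.any(clipped):
        import logging

        logging.getLogger(__name__).info(
            "clipped %d CDF values before inversion", int(clipped.sum())
        )
    u = np.clip(u, CDF_CLIP, 1.0 - CDF_CLIP)
    return stats.norm.ppf(u)


def order_statistic_medians(n: int) -> np.ndarray:
    """Uniform order-statistic medians (Filliben's approximation)."""
    i = np.arange(1, n + 1, dtype=float)
    m = (i - 0.3175) / (n + 0.365)
    m[0] = 1.0 - 0.5 ** (1.0 / n)
    m[-1] = 0.5 ** (1.0 / n)
    return m


def residual_summary(residuals: np.ndarray) -> ResidualSummary:
    """Moment summary (divisor n, raw kurtosis) plus the Filliben
    correlation of sorted residuals with normal order-statistic medians."""
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n < 8:
        raise ValueError("need at least 8 residuals")
    mean = float(np.mean(r))
    c = r - mean
    variance = float(np.mean(c ** 2))
    if variance <= 0:
        raise ValueError("zero residual variance")
    sd = math.sqrt(variance)
    skew = float(np.mean(c ** 3) / sd ** 3)
    kurt = float(np.mean(c ** 4) / sd ** 4)
    q = stats.norm.ppf(order_statistic_medians(n))
    filliben = float(np.corrcoef(np.sort(r), q)[0, 1])
    return ResidualSummary(mean, variance, skew, kurt, filliben)


def worm_plot_data(residuals: np.ndarray) -> pd.DataFrame:
    """Detrended Q-Q coordinates with a pointwise 95% band.

    x: normal quantiles of the order-statistic medians; y: sorted
    residuals minus x; band: +/- 1.96 sqrt(p(1-p)/n) / phi(x).
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n < 20:
        raise ValueError("need at least 20 residuals")
    p = order_statistic_medians(n)
    x = stats.norm.ppf(p)
    band = 1.96 * np.sqrt(p * (1.0 - p) / n) / stats.norm.pdf(x)
    return pd.DataFrame(
        {"x": x, "deviation": np.sort(r) - x, "band": band}
    )


def generalized_r2(
    fit: FittedModel, null_fit: Optional[FittedModel] = None
) -> float:
    """Generalised R-squared: 1 - exp((2/n)(l0 - l1)) with l0 the
    intercept-only log-likelihood of the same family on the same data."""
    if null_fit is None:
        l0 = -0.5 * fit.null_deviance()
    else:
        if null_fit.n != fit.n:
            raise ValueError("null fit is on a different number of observations")
        l0 = null_fit.loglik
    l1 = fit.loglik
    return float(1.0 - math.exp((2.0 / fit.n) * (l0 - l1)))


def icc_two_way(pairs: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> IccResult:
    """Single-measure ICCs from the two-way (subject x occasion) ANOVA.

    ``pairs``: one row per subject, two measurement columns (k = 2).
    consistency  = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    absolute     = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E)/n)
    with 95% confidence intervals from the standard F-based formulas.
    """
    X = np.asarray(pairs, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected a table with exactly two measurement columns")
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        raise ValueError("zero between-subject variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # consistency CI: F-interval on MSR/MSE
    if mse <= 0:
        ci_c = (icc_c, icc_c)
        ci_a = (icc_a, icc_a)
    else:
        fobs = msr / mse
        f_l = fobs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_u = fobs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        ci_c = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))

        # absolute-agreement CI (Satterthwaite df, McGraw & Wong)
        a = k * icc_a / (n * (1 - icc_a)) if icc_a < 1 else np.inf
        b = 1 + k * icc_a * (n - 1) / (n * (1 - icc_a)) if icc_a < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1)
                + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = (
                n * (msr - f_star_l * mse)
                / (
                    f_star_l * (k * msc + (k * n - k - n) * mse)
                    + n * msr
                )
            )
            upper = (
                n * (f_star_u * msr - mse)
                / (
                    k * msc
                    + (k * n - k - n) * mse
                    + n * f_star_u * msr
                )
            )
            ci_a = (lower, upper)
        else:
            ci_a = (icc_a, icc_a)
    return IccResult(
        icc_absolute=float(icc_a),
        icc_consistency=float(icc_c),
        ci_absolute=(float(ci_a[0]), float(ci_a[1])),
        ci_consistency=(float(ci_c[0]), float(ci_c[1])),
    )
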