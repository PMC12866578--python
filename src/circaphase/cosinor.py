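"""Single-component cosinor regression.

The cosinor model for a signal y observed at times t (hours) with a fixed
period T is the linear model

    y(t) = M + beta_c * cos(2*pi*t/T) + beta_s * sin(2*pi*t/T) + eps

whose trigonometric reparameterization is y = M + A*cos(2*pi*t/T - phi) with
amplitude A = sqrt(beta_c^2 + beta_s^2) and acrophase phi = atan2(beta_s,
beta_c).  Rhythmicity is assessed with the zero-amplitude F-test of this
model against the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CosinorFit", "fit_cosinor", "fit_cosinor_grid", "cosinor_pvalues"]


@dataclass
class CosinorFit:
    """Fitted cosinor parameters for one gene."""

    period: float  # T, hours
    mesor: float  # midline level M
    amplitude: float  # A >= 0
    acrophase_rad: float  # phi in [0, 2*pi)
    p_value: float  # zero-amplitude F-test
    beta: np.ndarray  # (mesor, beta_c, beta_s)
    cov: np.ndarray  # asymptotic covariance of beta (3x3)
    rss: float
    fitted: np.ndarray

    @property
    def peak_h(self) -> float:
        """Time of the fitted maximum within [0, period)."""
        return (self.acrophase_rad / (2.0 * np.pi) * self.period) % self.period

    @property
    def trough_h(self) -> float:
        """Time of the fitted minimum within [0, period)."""
        return (self.peak_h + self.period / 2.0) % self.period


def _design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi * t / period
    return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])


def _f_test(rss1: float, rss0: float, n: int) -> float:
    """F-test of the 3-parameter cosinor against the intercept-only model."""
    df1, df2 = 2, n - 3
    if df2 <= 0:
        return 1.0
    rss1 = max(rss1, 0.0)
    if rss1 <= np.finfo(float).tiny * max(1.0, rss0):
        return 0.0 if rss0 > rss1 else 1.0
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    return float(stats.f.sf(max(f, 0.0), df1, df2))


def fit_cosinor(y: np.ndarray, t: np.ndarray, period: float = 24.0) -> CosinorFit:
    """Least-squares cosinor fit of one series at a fixed period."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("cosinor fit needs at least 4 observations")
    X = _design(t, period)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient cosinor design")
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    p = _f_test(rss, rss0, n)
    sigma2 = rss / max(n - 3, 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    amplitude = float(np.hypot(beta[1], beta[2]))
    acro = float(np.arctan2(beta[2], beta[1]) % (2.0 * np.pi))
    return CosinorFit(
        period=float(period),
        mesor=float(beta[0]),
        amplitude=amplitude,
        acrophase_rad=acro,
        p_value=p,
        beta=beta,
        cov=sigma2 * xtx_inv,
        rss=rss,
        fitted=fitted,
    )


def fit_cosinor_grid(
    y: np.ndarray,
    t: np.ndarray,
    periods=tuple(range(20, 29)),
) -> CosinorFit:
    """Fit at every candidate period; keep the fit with the smallest RSS."""
    best: CosinorFit | None = None
    for T in periods:
        fit = fit_cosinor(y, t, period=float(T))
        if best is None or fit.rss < best.rss:
            best = fit
    return best


def cosinor_pvalues(
    values: np.ndarray, t: np.ndarray, period: float = 24.0
) -> np.ndarray:
    """Vectorized zero-amplitude F-test p-values for many genes at once.

    ``values`` is genes x samples; returns one p-value per row.
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    n = values.shape[1]
    X = _design(t, period)
    beta, _, _, _ = np.linalg.lstsq(X, values.T, rcond=None)
    fitted = (X @ beta).T
    rss1 = ((values - fitted) ** 2).sum(axis=1)
    rss0 = ((values - values.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = 2, n - 3
    if df2 <= 0:
        return np.ones(values.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
    f = np.where(rss1 <= np.finfo(float).tiny * np.maximum(1.0, rss0), np.inf, f)
    return stats.f.sf(np.maximum(f, 0.0), df1, df2)
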