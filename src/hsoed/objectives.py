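"""Error indexes, the accuracy-vs-cost objective and goodness-of-fit tools.

RMSE and the weighted residual sum of squared errors (wRSSE)

    φ(p) = Σ_k ((y_k − ŷ_k)/σ_k)²

quantify fit quality; under the true model with known Gaussian noise, φ
follows a χ² distribution with r = n_data − n_params degrees of freedom, which
yields the goodness-of-fit p-value.  The sample-size objective trades accuracy
against measurement cost:

    J(n_m) = Σ_i (y_i − ŷ_i)² + λ (n_m − n_p)/n_m,

with the penalty ratio normalized by the number of time points n_m (so it
saturates at 1) and λ ≥ 0 the cost coefficient.  The accuracy term is the raw
residual sum of squares by default, with a σ-weighted variant behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "rmse",
    "wrsse",
    "SampleSizeCost",
    "sample_size_cost",
    "gof_chi2",
    "qq_points",
    "FitDiagnostics",
    "fit_diagnostics",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and yhat must be equal-length nonempty 1-D arrays")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root-mean-square error between measured and predicted output."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def wrsse(y, yhat, sigma) -> float:
    """Weighted residual sum of squared errors φ = Σ ((y−ŷ)/σ)²."""
    y, yhat = _pair(y, yhat)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape)
    if np.any(sigma <= 0):
        raise ValueError("all σ must be positive")
    return float(np.sum(((y - yhat) / sigma) ** 2))


class SampleSizeCost(NamedTuple):
    total: float
    accuracy: float
    penalty: float


def sample_size_cost(
    residuals,
    n_m: int,
    n_p: int,
    lam: float,
    sigmas=None,
    weighted: bool = False,
) -> SampleSizeCost:
    """Accuracy-plus-cost objective J(n_m); the penalty term is returned
    separately alongside the total.

    ``weighted=True`` uses the σ-weighted residual sum instead of the raw one
    (requires ``sigmas``).
    """
    if n_p < 1 or n_m <= n_p:
        raise ValueError("need n_m > n_p ≥ 1")
    if lam < 0:
        raise ValueError("λ must be non-negative")
    r = np.asarray(residuals, dtype=float)
    if weighted:
        if sigmas is None:
            raise ValueError("weighted accuracy term requires sigmas")
        sig = np.broadcast_to(np.asarray(sigmas, dtype=float), r.shape)
        if np.any(sig <= 0):
            raise ValueError("all σ must be positive")
        accuracy = float(np.sum((r / sig) ** 2))
    else:
        accuracy = float(np.sum(r ** 2))
    penalty = lam * (n_m - n_p) / n_m
    return SampleSizeCost(accuracy + penalty, accuracy, penalty)


def gof_chi2(phi: float, n_data: int, n_params: int) -> tuple[int, float]:
    """χ² goodness-of-fit: dof = n_data − n_params and the upper-tail
    probability of the weighted residual statistic φ."""
    dof = n_data - n_params
    if dof < 1:
        raise ValueError("need n_data > n_params")
    if phi < 0:
        raise ValueError("φ must be non-negative")
    return dof, float(stats.chi2.sf(phi, dof))


def qq_points(residuals) -> tuple[np.ndarray, np.ndarray]:
    """Normal QQ pairs: standard-normal quantiles at plotting positions
    (i − 0.5)/n against the sorted residuals."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    if n < 3:
        raise ValueError("need at least 3 residuals")
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, r


@dataclass
class FitDiagnostics:
    """Bundle of fit-quality diagnostics for one estimated model."""

    rmse: float
    wrsse: float
    residuals: np.ndarray
    dof: int
    chi2_pvalue: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "wrsse": self.wrsse,
            "dof": self.dof,
            "chi2_pvalue": self.chi2_pvalue,
        }


def fit_diagnostics(y, yhat, sigma, n_params: int) -> FitDiagnostics:
    """Compute RMSE, wRSSE, the χ² GOF p-value and QQ pairs in one pass."""
    y, yhat = _pair(y, yhat)
    res = y - yhat
    phi = wrsse(y, yhat, sigma)
    dof, pval = gof_chi2(phi, len(y), n_params)
    theo, samp = qq_points(res)
    return FitDiagnostics(
        rmse=rmse(y, yhat),
        wrsse=phi,
        residuals=res,
        dof=dof,
        chi2_pvalue=pval,
        qq_theoretical=theo,
        qq_sample=samp,
    )
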