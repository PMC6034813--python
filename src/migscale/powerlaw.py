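"""Power-law (allometric) scaling fits for migration quantities.

The central relation is ``X = alpha * P^beta`` between a per-city
migration quantity ``X`` (outflow, inflow to a size class, international
arrivals, ...) and the city population ``P``.  Fitting is ordinary least
squares after taking logarithms of both sides, so the reported intercept
is ``ln(alpha)``; ``beta < 1`` (sublinear) means the per-capita quantity
``X/P = alpha * P^(beta-1)`` falls with city size, ``beta > 1``
(superlinear) means it rises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerLawFit",
    "EstimationError",
    "fit_power_law",
    "alpha_from_log",
    "per_capita_rate",
    "rate_ratio",
    "classify_regime",
    "fits_to_frame",
]


class EstimationError(ValueError):
    """Raised when a fit is infeasible (too few points, degenerate design)."""


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log OLS fit of ``X = alpha * P^beta``.

    ``log_alpha_hat`` is the natural-log intercept ``ln(alpha)``;
    ``adj_r2`` is the adjusted R-squared for one predictor,
    ``1 - (1 - R^2)(n - 1)/(n - 2)``.  Points with ``X = 0`` are dropped
    before fitting (their logarithm is undefined) and counted in
    ``n_dropped_zeros``.
    """

    beta_hat: float
    se_beta: float
    log_alpha_hat: float
    se_log_alpha: float
    adj_r2: float
    n_obs: int
    n_dropped_zeros: int = 0


def fit_power_law(populations, values) -> PowerLawFit:
    """OLS of ``ln(value)`` on ``ln(population)``.

    Parameters
    ----------
    populations
        Strictly positive city populations.
    values
        Nonnegative migration quantities; zeros are dropped and counted.

    Raises
    ------
    EstimationError
        Fewer than 3 usable points, or all populations equal.
    """
    P = np.asarray(populations, dtype=float)
    X = np.asarray(values, dtype=float)
    if P.shape != X.shape or P.ndim != 1:
        raise EstimationError("populations and values must be 1-d vectors of equal length")
    if (P <= 0).any():
        raise EstimationError("populations must be strictly positive")
    if (X < 0).any():
        raise EstimationError("values must be nonnegative")
    keep = X > 0
    n_dropped = int((~keep).sum())
    P, X = P[keep], X[keep]
    n = P.size
    if n < 3:
        raise EstimationError(f"need at least 3 points with positive values, have {n}")
    logP = np.log(P)
    logX = np.log(X)
    if np.ptp(logP) == 0.0:
        raise EstimationError("degenerate design: all populations are equal")
    res = stats.linregress(logP, logX)
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return PowerLawFit(
        beta_hat=float(res.slope),
        se_beta=float(res.stderr),
        log_alpha_hat=float(res.intercept),
        se_log_alpha=float(res.intercept_stderr),
        adj_r2=float(adj_r2),
        n_obs=n,
        n_dropped_zeros=n_dropped,
    )


def alpha_from_log(fit: PowerLawFit) -> float:
    """Back-transform the natural-log intercept: ``alpha = exp(ln alpha)``."""
    return float(np.exp(fit.log_alpha_hat))


def per_capita_rate(fit: PowerLawFit, P) -> Union[float, np.ndarray]:
    """Per-capita annual migration probability ``alpha * P^(beta - 1)``.

    Clipped to [0, 1] (the number of leavers cannot exceed the residents);
    a clip is reported with a ``RuntimeWarning``.
    """
    P_arr = np.asarray(P, dtype=float)
    if (P_arr <= 0).any():
        raise ValueError("population must be strictly positive")
    rate = np.exp(fit.log_alpha_hat + (fit.beta_hat - 1.0) * np.log(P_arr))
    if (rate > 1.0).any() or (rate < 0.0).any():
        warnings.warn(
            "per-capita rate clipped to [0, 1]; parameters extrapolated beyond validity",
            RuntimeWarning,
            stacklevel=2,
        )
        rate = np.clip(rate, 0.0, 1.0)
    return float(rate) if np.isscalar(P) else rate


def rate_ratio(fit: Union[PowerLawFit, float], P1, P2) -> float:
    """Per-capita rate ratio ``(P1/P2)^(beta - 1)``; independent of alpha.

    ``fit`` may be a :class:`PowerLawFit` or a bare exponent ``beta``.
    """
    beta = fit.beta_hat if isinstance(fit, PowerLawFit) else float(fit)
    if P1 <= 0 or P2 <= 0:
        raise ValueError("populations must be strictly positive")
    return float((P1 / P2) ** (beta - 1.0))


def classify_regime(fit: PowerLawFit, z: float = 2.0) -> str:
    """Classify the exponent against 1 at ``z`` standard errors.

    Returns ``"superlinear"`` if ``beta - z*se > 1``, ``"sublinear"`` if
    ``beta + z*se < 1``, else ``"linear-indistinguishable"``.
    """
    if fit.beta_hat - z * fit.se_beta > 1.0:
        return "superlinear"
    if fit.beta_hat + z * fit.se_beta < 1.0:
        return "sublinear"
    return "linear-indistinguishable"


def fits_to_frame(fits: Mapping[str, PowerLawFit]) -> pd.DataFrame:
    """Tabulate named fits (one row per scaling relation) for CSV export."""
    rows = [
        {
            "relation": name,
            "beta": f.beta_hat,
            "se_beta": f.se_beta,
            "log_alpha": f.log_alpha_hat,
            "se_log_alpha": f.se_log_alpha,
            "adj_r2": f.adj_r2,
            "n_obs": f.n_obs,
        }
        for name, f in fits.items()
    ]
    return pd.DataFrame(rows)
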