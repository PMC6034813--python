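"""Model-comparison metrics and bias diagnostics for OD flow predictions.

Predictions are compared cell by cell against the observed OD matrix:
mean square error over all ordered off-diagonal pairs (``n(n-1)`` cells;
the denominator is recorded so absolute values are interpretable),
maximum absolute error, and per-city marginal scatters
(observed vs predicted out/inflows) from which a small-city bias — the
mean signed error of predicted outflows over the smallest size quantile —
is computed.  Real-valued predictions are compared unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .datamodel import CitySystem, FlowMatrix

__all__ = ["EvalReport", "compare_flows", "small_city_bias"]


@dataclass
class EvalReport:
    """Flow-prediction quality: MSE, max error and per-city marginals."""

    mse: float
    max_abs_error: float
    per_city: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"mse": self.mse, "max_abs_error": self.max_abs_error, **self.meta}]
        )


def compare_flows(
    predicted: Union[np.ndarray, FlowMatrix],
    observed: FlowMatrix,
    system: CitySystem,
) -> EvalReport:
    """Compare a predicted flow matrix against observed migration.

    ``predicted`` may be a real-valued matrix (gravity, radiation) or a
    :class:`FlowMatrix` (simulator output); city sets must match.
    """
    if isinstance(predicted, FlowMatrix):
        if predicted.ids != observed.ids:
            raise ValueError(
                "city sets differ between predicted and observed flow matrices"
            )
        F = predicted.counts.astype(float)
    else:
        F = np.asarray(predicted, dtype=float)
        if F.shape != observed.counts.shape:
            raise ValueError(
                f"predicted shape {F.shape} does not match observed {observed.counts.shape}"
            )
    if observed.ids != system.ids:
        raise ValueError("observed flow matrix does not match the city system")
    F = F.copy()
    np.fill_diagonal(F, 0.0)
    X = observed.counts.astype(float)
    off = ~np.eye(observed.n, dtype=bool)
    err = F[off] - X[off]
    per_city = pd.DataFrame(
        {
            "city": list(system.ids),
            "population": system.populations,
            "observed_out": X.sum(axis=1),
            "predicted_out": F.sum(axis=1),
            "observed_in": X.sum(axis=0),
            "predicted_in": F.sum(axis=0),
        }
    )
    return EvalReport(
        mse=float(np.mean(err**2)),
        max_abs_error=float(np.max(np.abs(err))) if err.size else 0.0,
        per_city=per_city,
        meta={"n_pairs": int(off.sum()), "mse_denominator": "ordered off-diagonal pairs"},
    )


def small_city_bias(report: EvalReport, quantile: float = 0.25) -> float:
    """Mean signed outflow error (predicted - observed) in the smallest cities.

    Cities at or below the ``quantile`` of the population distribution are
    selected; ``quantile=1.0`` gives the overall mean error.  A negative
    value means the model underestimates small-city out-migration.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    pop = report.per_city["population"].to_numpy()
    threshold = np.quantile(pop, quantile)
    sel = pop <= threshold
    if not sel.any():
        raise ValueError("no cities in the requested quantile")
    diff = report.per_city["predicted_out"].to_numpy() - report.per_city[
        "observed_out"
    ].to_numpy()
    return float(diff[sel].mean())
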