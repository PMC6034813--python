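"""Packaged parameter bundles.

The default bundle, ``us_2018_params``, carries the published
log-log OLS coefficients for US metropolitan migration (385 MSAs):
out-migration and countryside relations, destination fits conditioned on
origin-size thresholds, and international inflow fits by world region.
All intercepts are natural logarithms of alpha.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Union

import numpy as np
import yaml

from .beta_curve import BetaCurve
from .models import ScalingParams
from .powerlaw import PowerLawFit

__all__ = ["load_bundle", "load_us_2018_params", "threshold_beta_curve"]

_DEFAULT_BUNDLE = "us_2018_params.yaml"


def _fit_from_row(row: dict, n_obs: int) -> PowerLawFit:
    return PowerLawFit(
        beta_hat=float(row["beta"]),
        se_beta=float(row["se_beta"]),
        log_alpha_hat=float(row["log_alpha"]),
        se_log_alpha=float(row["se_log_alpha"]),
        adj_r2=float(row["adj_r2"]),
        n_obs=n_obs,
    )


def load_bundle(name_or_path: Union[str, None] = None) -> dict:
    """Load a raw parameter bundle (packaged default, or a YAML path)."""
    if name_or_path is None:
        text = files("migscale.data").joinpath(_DEFAULT_BUNDLE).read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def threshold_beta_curve(bundle: dict) -> BetaCurve:
    """Build a destination-exponent curve from threshold-conditioned fits.

    Each "origin below threshold T" fit is anchored at the geometric
    midpoint of (P_min, T) and each "origin above T" fit at the geometric
    midpoint of (T, P_max), yielding a piecewise curve that rises through
    1 between one and a few million inhabitants.
    """
    lo, hi = bundle["population_range"]
    pops, betas = [], []
    for row in bundle["outflow"]["destination_by_origin_size"]:
        T = float(row["threshold"])
        anchor = np.sqrt(lo * T) if row["kind"] == "below" else np.sqrt(T * hi)
        pops.append(anchor)
        betas.append(float(row["beta"]))
    return BetaCurve.from_points(pops, betas)


def load_us_2018_params(name_or_path: Union[str, None] = None) -> ScalingParams:
    """Assemble a :class:`ScalingParams` from a bundle (packaged default)."""
    bundle = load_bundle(name_or_path)
    n_obs = int(bundle.get("n_cities", 385))
    return ScalingParams(
        leave_city_fit=_fit_from_row(bundle["outflow"]["leave_city"], n_obs),
        to_countryside_fit=_fit_from_row(bundle["outflow"]["to_countryside"], n_obs),
        beta_curve=threshold_beta_curve(bundle),
        p_countryside_leave=float(bundle["p_countryside_leave"]),
        from_countryside_dest_beta=float(bundle["inflow"]["from_countryside"]["beta"]),
        international_dest_fits={
            region: _fit_from_row(row, n_obs)
            for region, row in bundle["international"].items()
        },
    )
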