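"""Flux models of city-to-city migration behind one prediction contract.

Four models are provided:

* **scaling** — a two-step stochastic simulator driven purely by city
  size.  Step 1: each resident of city ``i`` decides to stay, move to
  another city (probability ``alpha * P_i^(beta-1)``, sublinear) or move
  to the countryside (a second sublinear relation).  Step 2: movers pick
  a destination with probability proportional to ``P_j^beta(P_i)``,
  where the exponent comes from the averaged moving-window curve.
  Countryside residents enter the cities with a fixed per-capita
  probability and a sublinear destination kernel; international arrivals
  are allocated superlinearly by destination size.  The process is
  Markovian: decisions depend only on the current location.
* **gravity** — deterministic flux ``F_ij = a * P_i * P_j / d_ij^b``.
* **radiation** — the parameter-free intervening-opportunities flux,
  using the population located closer to the origin than the destination.
* **gravity-scaling** — the hybrid: the scaling model's destination
  probabilities divided by distance and renormalized,
  ``pi'_ij = C * pi_ij / d_ij``, keeping step 1 unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .beta_curve import BetaCurve, beta_at
from .datamodel import REGIONS, CitySystem, FlowMatrix
from .powerlaw import EstimationError, PowerLawFit, per_capita_rate

__all__ = [
    "COUNTRYSIDE",
    "ScalingParams",
    "GravityParams",
    "SimulationConfig",
    "SimulationResult",
    "step1_leave_probs",
    "destination_probs_scaling",
    "destination_probs_gravity_scaling",
    "expected_flow_matrix",
    "simulate_two_step",
    "international_inflow",
    "gravity_flux",
    "fit_gravity",
    "intervening_population",
    "radiation_flux",
]

#: Sentinel origin for countryside-to-city destination kernels.
COUNTRYSIDE = "countryside"


@dataclass
class ScalingParams:
    """Parameter bundle for the scaling (and gravity-scaling) model.

    ``leave_city_fit`` gives the per-capita probability of migrating to
    another city; ``to_countryside_fit`` the per-capita probability of
    moving to the countryside; ``p_countryside_leave`` the annual
    probability that a countryside resident moves to a city;
    ``from_countryside_dest_beta`` the (sublinear) destination exponent
    for those movers; ``beta_curve`` the origin-size-dependent destination
    exponent for city-to-city moves; ``international_dest_fits`` the
    per-world-region destination fits for arrivals from abroad.
    """

    leave_city_fit: PowerLawFit
    to_countryside_fit: PowerLawFit
    beta_curve: BetaCurve
    p_countryside_leave: float = 0.0322
    from_countryside_dest_beta: float = 0.5971
    international_dest_fits: dict[str, PowerLawFit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_countryside_leave <= 1.0:
            raise ValueError("p_countryside_leave must be in [0, 1]")
        for region in self.international_dest_fits:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


@dataclass(frozen=True)
class GravityParams:
    """Gravity-model constants: flux scale ``a`` and distance exponent ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation protocol: person-sampling fraction, replicates, seed.

    A fraction of each population is simulated (binomial thinning) and
    counts rescaled by ``1/sample_fraction``, keeping expectations exact
    while reducing cost; replicates are aggregated cellwise by median.
    """

    sample_fraction: float = 0.2
    n_reps: int = 100
    rng_seed: int = 0
    keep_reps: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class SimulationResult:
    """Median flows (rescaled to the full population) plus countryside channels."""

    flows: FlowMatrix
    to_countryside: np.ndarray
    from_countryside: np.ndarray
    per_rep_flows: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


def step1_leave_probs(
    system: CitySystem, params: ScalingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-city (p_stay, p_to_city, p_to_countryside); each row sums to 1."""
    P = system.populations.astype(float)
    p_city = np.atleast_1d(per_capita_rate(params.leave_city_fit, P))
    p_cs = np.atleast_1d(per_capita_rate(params.to_countryside_fit, P))
    total = p_city + p_cs
    if (total > 1.0).any():
        bad = int(np.argmax(total))
        raise ValueError(
            f"leave probabilities exceed 1 for city {system.ids[bad]!r} "
            f"(P={system.cities[bad].population}): parameters extrapolated beyond validity"
        )
    return 1.0 - total, p_city, p_cs


def _scaling_weights(system: CitySystem, beta: float, exclude: Optional[int]) -> np.ndarray:
    logP = np.log(system.populations.astype(float))
    w = np.exp(beta * (logP - logP.max()))  # stabilised P^beta
    if exclude is not None:
        w[exclude] = 0.0
    return w


def destination_probs_scaling(
    origin: Union[int, str], system: CitySystem, params: ScalingParams
) -> np.ndarray:
    """Destination probability vector under the pure scaling kernel.

    For a city origin ``i``: proportional to ``P_j^beta(P_i)`` over
    ``j != i``.  For ``COUNTRYSIDE``: proportional to
    ``P_j^from_countryside_dest_beta`` over all cities.  For a world
    region name: proportional to ``P_j^beta_region``.
    """
    if origin == COUNTRYSIDE:
        beta = params.from_countryside_dest_beta
        exclude = None
    elif isinstance(origin, str):
        try:
            beta = params.international_dest_fits[origin].beta_hat
        except KeyError:
            raise KeyError(f"no international destination fit for region {origin!r}") from None
        exclude = None
    else:
        if system.n < 2:
            raise ValueError("need at least 2 cities for inter-city destinations")
        beta = beta_at(params.beta_curve, float(system.cities[origin].population))
        exclude = int(origin)
    w = _scaling_weights(system, beta, exclude)
    return w / w.sum()


def destination_probs_gravity_scaling(
    origin: int,
    system: CitySystem,
    params: ScalingParams,
    min_distance: Optional[float] = None,
) -> np.ndarray:
    """Scaling destination probabilities divided by distance, renormalized.

    ``pi'_ij = C * pi_ij / d_ij`` with ``C`` chosen so the vector sums to
    one.  Distances are floored at ``min_distance`` (default: the smallest
    positive inter-city distance) to guard against co-located cities; a
    zero distance with no usable floor is an error.
    """
    pi = destination_probs_scaling(origin, system, params)
    d = system.distance_matrix()[origin].astype(float).copy()
    floor = _distance_floor(system, min_distance)
    mask = np.arange(system.n) != origin
    if floor is None and (d[mask] == 0).any():
        raise ValueError("zero distance between distinct cities and no distance floor")
    if floor is not None:
        d = np.maximum(d, floor)
    w = np.where(mask, pi / d, 0.0)
    return w / w.sum()


def _distance_floor(system: CitySystem, min_distance: Optional[float]) -> Optional[float]:
    if min_distance is not None:
        return float(min_distance)
    d = system.distance_matrix()
    off = d[~np.eye(system.n, dtype=bool)]
    positive = off[off > 0]
    return float(positive.min()) if positive.size else None


def _destination_matrix(
    system: CitySystem,
    params: ScalingParams,
    kernel: str,
    min_distance: Optional[float] = None,
) -> np.ndarray:
    if kernel == "scaling":
        rows = [destination_probs_scaling(i, system, params) for i in range(system.n)]
    elif kernel == "gravity-scaling":
        rows = [
            destination_probs_gravity_scaling(i, system, params, min_distance)
            for i in range(system.n)
        ]
    else:
        raise ValueError(f"unknown kernel {kernel!r}; expected 'scaling' or 'gravity-scaling'")
    return np.vstack(rows)


def expected_flow_matrix(
    system: CitySystem,
    params: ScalingParams,
    kernel: str = "scaling",
    min_distance: Optional[float] = None,
) -> np.ndarray:
    """Deterministic expected inter-city flows ``P_i * p_to_city(i) * pi_ij``."""
    _, p_city, _ = step1_leave_probs(system, params)
    pi = _destination_matrix(system, params, kernel, min_distance)
    return system.populations.astype(float)[:, None] * p_city[:, None] * pi


def simulate_two_step(
    system: CitySystem,
    params: ScalingParams,
    config: SimulationConfig,
    kernel: str = "scaling",
    min_distance: Optional[float] = None,
) -> SimulationResult:
    """Run the two-step migration simulator.

    Per replicate and per city: a single categorical draw splits the
    sampled residents into city-bound movers, countryside-bound movers
    and stayers (the two leaving channels compete); city-bound movers are
    allocated across destinations by a multinomial draw with the chosen
    kernel.  Countryside residents enter the cities by a binomial draw at
    ``p_countryside_leave`` allocated with the countryside kernel.  All
    counts are rescaled by ``1/sample_fraction``; replicates are
    aggregated cellwise by median.  No births, deaths or emigration.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = system.n
    P = system.populations
    _, p_city, p_cs = step1_leave_probs(system, params)
    step1_pvals = np.stack([p_city, p_cs, 1.0 - p_city - p_cs], axis=1)
    pi = _destination_matrix(system, params, kernel, min_distance)
    cs_probs = destination_probs_scaling(COUNTRYSIDE, system, params)
    f = config.sample_fraction
    n_sampled = np.rint(f * P).astype(np.int64)
    cs_sampled = int(round(f * system.countryside_population))
    scale = 1.0 / f

    flows = np.zeros((config.n_reps, n, n), dtype=np.int64)
    to_cs = np.zeros((config.n_reps, n), dtype=np.int64)
    from_cs = np.zeros((config.n_reps, n), dtype=np.int64)
    for r in range(config.n_reps):
        for i in range(n):
            movers_city, movers_cs, _ = rng.multinomial(n_sampled[i], step1_pvals[i])
            # leavers can never exceed residents: the categorical draw
            # partitions the sampled population
            if movers_city:
                flows[r, i] = rng.multinomial(movers_city, pi[i])
            to_cs[r, i] = movers_cs
        if cs_sampled and system.countryside_population:
            cs_movers = rng.binomial(cs_sampled, params.p_countryside_leave)
            if cs_movers:
                from_cs[r] = rng.multinomial(cs_movers, cs_probs)

    flows_scaled = flows * scale
    median_flows = np.rint(np.median(flows_scaled, axis=0)).astype(np.int64)
    np.fill_diagonal(median_flows, 0)
    result = SimulationResult(
        flows=FlowMatrix(median_flows, system.ids),
        to_countryside=np.rint(np.median(to_cs * scale, axis=0)).astype(np.int64),
        from_countryside=np.rint(np.median(from_cs * scale, axis=0)).astype(np.int64),
        per_rep_flows=flows_scaled if config.keep_reps else None,
        meta={
            "kernel": kernel,
            "sample_fraction": f,
            "n_reps": config.n_reps,
            "rng_seed": config.rng_seed,
        },
    )
    return result


def international_inflow(
    system: CitySystem,
    params: ScalingParams,
    totals: Mapping[str, int],
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> pd.DataFrame:
    """Allocate each region's total arrivals across cities.

    Multinomial allocation with probabilities proportional to
    ``P_j^beta_region`` (superlinear regions concentrate arrivals in the
    largest cities).  Returns a city-by-region DataFrame of counts.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = {}
    for region, total in totals.items():
        probs = destination_probs_scaling(region, system, params)
        out[region] = gen.multinomial(int(total), probs)
    return pd.DataFrame(out, index=list(system.ids))


def gravity_flux(
    system: CitySystem, params: GravityParams, min_distance: Optional[float] = None
) -> np.ndarray:
    """Gravity prediction ``F_ij = a * P_i * P_j / d_ij^b`` (symmetric, real-valued)."""
    d = system.distance_matrix().astype(float).copy()
    off = ~np.eye(system.n, dtype=bool)
    floor = _distance_floor(system, min_distance)
    if (d[off] == 0).any():
        if floor is None or floor <= 0:
            raise ValueError("zero distance between distinct cities and no distance floor")
        d = np.maximum(d, floor)
    P = system.populations.astype(float)
    with np.errstate(divide="ignore"):
        F = params.a * np.outer(P, P) / d**params.b
    np.fill_diagonal(F, 0.0)
    return F


def fit_gravity(
    system: CitySystem,
    observed: FlowMatrix,
    b_bounds: tuple[float, float] = (0.0, 3.0),
    n_grid: int = 31,
    min_distance: Optional[float] = None,
) -> GravityParams:
    """Least-squares gravity fit by minimising the mean square error.

    For each candidate ``b`` the optimal ``a`` is available in closed form
    (the model is linear in ``a``); a grid over ``b_bounds`` seeds a
    derivative-free Nelder-Mead polish over ``(ln a, b)``.  Deterministic
    given the data and settings.
    """
    X = observed.counts.astype(float)
    off = ~np.eye(system.n, dtype=bool)
    if X[off].sum() == 0:
        raise EstimationError("cannot fit gravity to an all-zero flow matrix")
    d = system.distance_matrix().astype(float).copy()
    floor = _distance_floor(system, min_distance)
    if floor is not None:
        d = np.maximum(d, floor)
    if (d[off] <= 0).any():
        raise ValueError("zero distance between distinct cities and no distance floor")
    PP = np.outer(system.populations.astype(float), system.populations.astype(float))
    x = X[off]
    pp = PP[off]
    dd = d[off]
    logd = np.log(dd)

    def a_closed_form(b: float) -> float:
        g = pp * np.exp(-b * logd)
        return float((x * g).sum() / (g * g).sum())

    def mse(log_a: float, b: float) -> float:
        if b < b_bounds[0] - 1e-9:
            return np.inf
        g = pp * np.exp(-b * logd)
        resid = np.exp(log_a) * g - x
        return float(np.mean(resid**2))

    grid = np.linspace(b_bounds[0], b_bounds[1], n_grid)
    best_b = min(grid, key=lambda b: mse(np.log(max(a_closed_form(b), 1e-300)), b))
    a0 = max(a_closed_form(best_b), 1e-300)
    res = optimize.minimize(
        lambda t: mse(t[0], t[1]),
        x0=np.array([np.log(a0), best_b]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    log_a, b = res.x
    b = max(b, 0.0)
    return GravityParams(a=float(np.exp(log_a)), b=float(b))


def intervening_population(system: CitySystem, i: int, j: int) -> int:
    """Population living strictly closer to ``i`` than ``j`` is, excluding both."""
    if i == j:
        raise ValueError("origin and destination must differ")
    d = system.distance_matrix()
    mask = d[i] < d[i, j]
    mask[i] = False
    mask[j] = False
    return int(system.populations[mask].sum())


def _intervening_matrix(system: CitySystem) -> np.ndarray:
    d = system.distance_matrix()
    P = system.populations.astype(float)
    n = system.n
    S = np.zeros((n, n))
    for i in range(n):
        closer = d[i][None, :] < d[i][:, None]  # closer[j, k]: d_ik < d_ij
        closer[:, i] = False
        np.fill_diagonal(closer, False)  # k == j never counts (d_ij < d_ij is false anyway)
        S[i] = closer @ P
    np.fill_diagonal(S, 0.0)
    return S


def radiation_flux(system: CitySystem, outflows) -> np.ndarray:
    """Parameter-free radiation prediction, rows renormalized to ``outflows``.

    ``F_ij = X_i* * P_i P_j / [(P_i + s_ij)(P_i + P_j + s_ij)]`` with
    ``s_ij`` the intervening population.  In a finite system the raw
    destination weights do not sum to one, so each row is renormalized to
    the supplied outflow.
    """
    out = np.asarray(outflows, dtype=float)
    P = system.populations.astype(float)
    S = _intervening_matrix(system)
    W = np.outer(P, P) / ((P[:, None] + S) * (P[:, None] + P[None, :] + S))
    np.fill_diagonal(W, 0.0)
    row = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(row[:, None] > 0, W * (out / np.where(row > 0, row, 1.0))[:, None], 0.0)
    return F
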