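"""Core containers for city systems and origin-destination migration flows.

A *city* is a high-density urban area (a metropolitan statistical area in
the US context) identified by an opaque string id, with a resident
population and a pair of coordinates.  A :class:`CitySystem` bundles the
cities of one country/region together with the aggregate *countryside*
population (residents of settlements too small to count as cities) and a
cached inter-city distance matrix.

Migration counts live in a :class:`FlowMatrix`: an ``n x n`` integer
origin-destination (OD) matrix ``X[i, j]`` = number of migrants from city
``i`` to city ``j`` in one period.  Moves within the same urban area are
not migration, so the diagonal is structurally zero.

Files are plain delimited text: a city table ``id,population,lon,lat`` and
a long-form flow table ``origin,destination,count`` (zero cells omitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Region keys accepted for international inflows.
REGIONS = ("All", "Africa", "Asia", "Americas", "Europe", "Oceania")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


@dataclass(frozen=True)
class City:
    """One city: opaque id, resident population, coordinates in degrees."""

    id: str
    population: int
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValidationError(
                f"city {self.id!r}: population must be >= 1, got {self.population}"
            )
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"city {self.id!r}: lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"city {self.id!r}: lon {self.lon} outside [-180, 180]")


class CitySystem:
    """An ordered collection of cities plus the countryside population pool.

    Parameters
    ----------
    cities
        Cities in a stable order; ids must be unique.
    countryside_population
        Aggregate population of settlements below the city threshold,
        treated as a single origin/destination with no defined distance.
    metric
        ``"haversine"`` treats coordinates as lon/lat degrees and returns
        great-circle distances in km (Earth radius 6371.0 km);
        ``"euclidean"`` treats them as planar coordinates (useful for
        synthetic systems) and returns plane distances in the same units.
    """

    def __init__(
        self,
        cities: Iterable[City],
        countryside_population: int = 0,
        metric: str = "haversine",
    ) -> None:
        cities = list(cities)
        if not cities:
            raise ValidationError("a CitySystem needs at least one city")
        ids = [c.id for c in cities]
        seen: set[str] = set()
        for cid in ids:
            if cid in seen:
                raise ValidationError(f"duplicate city id {cid!r}")
            seen.add(cid)
        if countryside_population < 0:
            raise ValidationError("countryside_population must be >= 0")
        if metric not in ("haversine", "euclidean"):
            raise ValidationError(f"unknown metric {metric!r}")
        self.cities: list[City] = cities
        self.countryside_population = int(countryside_population)
        self.metric = metric
        self._ids: tuple[str, ...] = tuple(ids)
        self._index: dict[str, int] = {cid: k for k, cid in enumerate(ids)}
        self._dist: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.cities)

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.cities], dtype=np.int64)

    def index(self, city_id: str) -> int:
        try:
            return self._index[city_id]
        except KeyError:
            raise KeyError(f"unknown city id {city_id!r}") from None

    def distance_matrix(self) -> np.ndarray:
        """Cached symmetric distance matrix with zero diagonal (km)."""
        if self._dist is None:
            self._dist = distance_matrix(self)
        return self._dist

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CitySystem(n={self.n}, countryside={self.countryside_population}, "
            f"metric={self.metric!r})"
        )


def distance_matrix(system: CitySystem) -> np.ndarray:
    """Pairwise inter-city distances in km.

    Great-circle (haversine, R = 6371.0 km) for geographic systems,
    Euclidean for planar synthetic ones.  Symmetric, zero diagonal.
    """
    lon = np.array([c.lon for c in system.cities], dtype=float)
    lat = np.array([c.lat for c in system.cities], dtype=float)
    if system.metric == "euclidean":
        dx = lon[:, None] - lon[None, :]
        dy = lat[:, None] - lat[None, :]
        d = np.hypot(dx, dy)
    else:
        phi = np.radians(lat)
        lam = np.radians(lon)
        dphi = phi[:, None] - phi[None, :]
        dlam = lam[:, None] - lam[None, :]
        h = (
            np.sin(dphi / 2.0) ** 2
            + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
        )
        d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry against floating-point noise
    return (d + d.T) / 2.0


class FlowMatrix:
    """Integer OD migration counts ``X[i, j]`` with structurally zero diagonal."""

    def __init__(self, counts: np.ndarray, ids: Iterable[str]) -> None:
        counts = np.asarray(counts)
        ids = tuple(ids)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError(f"counts must be square, got shape {counts.shape}")
        if counts.shape[0] != len(ids):
            raise ValidationError("counts shape does not match number of ids")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.allclose(counts, np.rint(counts)):
                raise ValidationError("flow counts must be integers")
            counts = np.rint(counts)
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("flow counts must be >= 0")
        if np.diagonal(counts).any():
            raise ValidationError("diagonal flows (within-city moves) are not allowed")
        self.counts = counts
        self.ids = ids

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def outflows(self) -> np.ndarray:
        """Row sums X_i* (total out-migration per origin)."""
        return self.counts.sum(axis=1)

    @property
    def inflows(self) -> np.ndarray:
        """Column sums X_*j (total in-migration per destination)."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlowMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.counts, other.counts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FlowMatrix(n={self.n}, total={self.total})"


def marginals(flow: FlowMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(outflows X_i*, inflows X_*j)``; both sum to the total."""
    return flow.outflows, flow.inflows


@dataclass(frozen=True)
class AuxFlows:
    """Auxiliary flows outside the inter-city matrix, keyed by city id.

    ``to_countryside[i]`` and ``from_countryside[i]`` are per-city counts;
    ``international_in[(i, region)]`` counts arrivals from abroad by world
    region (region keys restricted to :data:`REGIONS`).
    """

    to_countryside: Mapping[str, int]
    from_countryside: Mapping[str, int]
    international_in: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for name, mapping in (
            ("to_countryside", self.to_countryside),
            ("from_countryside", self.from_countryside),
        ):
            for k, v in mapping.items():
                if v < 0:
                    raise ValidationError(f"{name}[{k!r}] must be >= 0, got {v}")
        for (cid, region), v in self.international_in.items():
            if region not in REGIONS:
                raise ValidationError(
                    f"unknown region {region!r} for city {cid!r}; expected one of {REGIONS}"
                )
            if v < 0:
                raise ValidationError(f"international_in[{cid!r}, {region!r}] must be >= 0")


_CITY_COLUMNS = ("id", "population", "lon", "lat")


def read_city_table(
    path,
    dialect: Mapping[str, str] | None = None,
    countryside_population: int = 0,
    metric: str = "haversine",
) -> CitySystem:
    """Read a city table CSV (columns ``id,population,lon,lat``).

    ``dialect`` maps the standard column names to the names used in the
    file, e.g. ``{"id": "GEOID", "population": "POP"}``.
    """
    colmap = {c: c for c in _CITY_COLUMNS}
    if dialect:
        colmap.update({k: v for k, v in dialect.items() if k in colmap})
    df = pd.read_csv(path, dtype={colmap["id"]: str})
    for std, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"city table is missing column {col!r} (for {std!r})")
    cities = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        pop = rec[colmap["population"]]
        if not (np.isreal(pop) and float(pop) == int(pop) and int(pop) > 0):
            raise ValidationError(
                f"row {row_idx}: population must be a positive integer, got {pop!r}"
            )
        try:
            cities.append(
                City(
                    id=str(rec[colmap["id"]]),
                    population=int(pop),
                    lon=float(rec[colmap["lon"]]),
                    lat=float(rec[colmap["lat"]]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row_idx}: {exc}") from None
    return CitySystem(cities, countryside_population=countryside_population, metric=metric)


def read_flow_matrix(path, system: CitySystem) -> FlowMatrix:
    """Read a long-form flow CSV (``origin,destination,count``).

    Unmentioned pairs are zero; repeated pairs are summed; diagonal records
    and negative counts are rejected; unknown ids raise ``KeyError``.
    """
    try:
        df = pd.read_csv(path, dtype={"origin": str, "destination": str})
    except pd.errors.EmptyDataError:
        return FlowMatrix(np.zeros((system.n, system.n), dtype=np.int64), system.ids)
    for col in ("origin", "destination", "count"):
        if col not in df.columns:
            raise SchemaError(f"flow table is missing column {col!r}")
    counts = np.zeros((system.n, system.n), dtype=np.int64)
    for row_idx, (orig, dest, cnt) in enumerate(
        zip(df["origin"], df["destination"], df["count"])
    ):
        i = system.index(orig)
        j = system.index(dest)
        if i == j:
            raise ValidationError(
                f"row {row_idx}: diagonal flow {orig!r}->{dest!r} is not migration"
            )
        if not (np.isreal(cnt) and float(cnt) == int(cnt)):
            raise ValidationError(f"row {row_idx}: count must be an integer, got {cnt!r}")
        if int(cnt) < 0:
            raise ValidationError(f"row {row_idx}: negative count {cnt}")
        counts[i, j] += int(cnt)
    return FlowMatrix(counts, system.ids)


def write_flow_matrix(flow: FlowMatrix, path) -> None:
    """Write a flow matrix as long-form CSV, omitting zero cells.

    ``read_flow_matrix(write_flow_matrix(x))`` reproduces ``x`` exactly.
    """
    i_idx, j_idx = np.nonzero(flow.counts)
    df = pd.DataFrame(
        {
            "origin": [flow.ids[i] for i in i_idx],
            "destination": [flow.ids[j] for j in j_idx],
            "count": flow.counts[i_idx, j_idx],
        }
    )
    df.to_csv(path, index=False)


def read_aux_flows(countryside_path=None, international_path=None) -> AuxFlows:
    """Read auxiliary flow CSVs.

    ``countryside_path``: columns ``id,to_countryside,from_countryside``;
    ``international_path``: columns ``id,region,count``.
    """
    to_cs: dict[str, int] = {}
    from_cs: dict[str, int] = {}
    intl: dict[tuple[str, str], int] = {}
    if countryside_path is not None:
        df = pd.read_csv(countryside_path, dtype={"id": str})
        for col in ("id", "to_countryside", "from_countryside"):
            if col not in df.columns:
                raise SchemaError(f"countryside table is missing column {col!r}")
        to_cs = {r.id: int(r.to_countryside) for r in df.itertuples(index=False)}
        from_cs = {r.id: int(r.from_countryside) for r in df.itertuples(index=False)}
    if international_path is not None:
        df = pd.read_csv(international_path, dtype={"id": str, "region": str})
        for col in ("id", "region", "count"):
            if col not in df.columns:
                raise SchemaError(f"international table is missing column {col!r}")
        for r in df.itertuples(index=False):
            intl[(r.id, r.region)] = intl.get((r.id, r.region), 0) + int(r.count)
    return AuxFlows(to_countryside=to_cs, from_countryside=from_cs, international_in=intl)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance between two lon/lat points, km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(min(h, 1.0)))
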