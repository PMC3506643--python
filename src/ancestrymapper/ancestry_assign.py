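"""Nearest-neighbor ancestry assignment and geographic comparisons.

An individual's AMid barcode places it in a fixed coordinate system, so
ancestry can be read off by ranking all database individuals by the
Euclidean distance between barcodes and inspecting the populations of
the closest few (ten, classically).  The tally over those neighbors is
the report; the top-tally population is offered as a deterministic call.

Geographic utilities support genetic-vs-geographic distance comparisons:
great-circle (haversine) distances, summed multi-leg land routes, and a
per-population table of median AMid toward a target reference against
geographic distance, with a Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .amid_core import AMidProfile, profiles_to_frame
from .errors import InvalidKError, InvalidRouteError, PanelMismatchError

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A location in decimal degrees."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class NeighborReport:
    """Ranked closest individuals in AMid space for one query."""

    query_sample_id: str
    neighbors: list[tuple[str, str, float]]  # (sample_id, population, distance)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.neighbors, columns=["sample_id", "population", "distance"]
        ).rename_axis("rank")


@dataclass
class AncestryCall:
    """Population tally over the k nearest neighbors plus the top call."""

    query_sample_id: str
    call: str
    tally: list[tuple[str, int, int]]  # (population, count, best rank)


def amid_distance(a: AMidProfile, b: AMidProfile, space: str = "normalized") -> float:
    """Euclidean distance between two AMid barcodes over the panel."""
    if a.population_names != b.population_names:
        raise PanelMismatchError(
            f"profiles {a.sample_id!r} and {b.sample_id!r} use different panels"
        )
    va = getattr(a, space)
    vb = getattr(b, space)
    return float(np.sqrt(((va - vb) ** 2).sum()))


def nearest_neighbors(
    query: AMidProfile,
    database_profiles: list[AMidProfile],
    populations: pd.Series | dict,
    k: int = 10,
    space: str = "normalized",
) -> NeighborReport:
    """The k database individuals closest to the query in AMid space.

    The query's own id is excluded from the database; ties in distance
    are broken by sample id, so the ranking is deterministic.
    """
    db = [p for p in database_profiles if p.sample_id != query.sample_id]
    if k > len(db):
        raise InvalidKError(f"k={k} exceeds database size {len(db)}")
    dists = [(amid_distance(query, p, space), p.sample_id) for p in db]
    order = sorted(range(len(db)), key=lambda i: dists[i])
    neighbors = [
        (db[i].sample_id, str(populations[db[i].sample_id]), dists[i][0])
        for i in order[:k]
    ]
    return NeighborReport(query.sample_id, neighbors)


def assign_ancestry(report: NeighborReport) -> AncestryCall:
    """Tally neighbor populations and call the top one.

    Tallies are sorted by count (descending) then by the best (smallest)
    rank at which the population appears, so an exact tie in counts goes
    to the population of the higher-ranked neighbor.
    """
    if not report.neighbors:
        raise ValueError("empty neighbor report")
    best_rank: dict[str, int] = {}
    counts: dict[str, int] = {}
    for rank, (_, pop, _) in enumerate(report.neighbors):
        counts[pop] = counts.get(pop, 0) + 1
        best_rank.setdefault(pop, rank)
    tally = sorted(
        ((pop, counts[pop], best_rank[pop]) for pop in counts),
        key=lambda t: (-t[1], t[2]),
    )
    return AncestryCall(report.query_sample_id, tally[0][0], tally)


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine distance on a sphere of radius 6371 km."""
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def route_distance(waypoints: list[GeoPoint]) -> float:
    """Sum of consecutive great-circle legs along an explicit route.

    Supports hand-built land routes (e.g. around oceans) given as
    waypoint lists; at least two waypoints are required.
    """
    if len(waypoints) < 2:
        raise InvalidRouteError("a route needs at least two waypoints")
    return sum(
        great_circle_km(p, q) for p, q in zip(waypoints[:-1], waypoints[1:])
    )


def genetic_vs_geographic(
    profiles: list[AMidProfile],
    metadata: pd.DataFrame,
    target_population: str,
    route_distances: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Median AMid toward a target reference vs. geographic distance.

    Per population: the median normalized AMid of its members at the
    target population's reference, and its geographic distance to the
    target population (from ``route_distances`` when given, otherwise
    the great-circle distance between per-population mean coordinates).
    Populations without coordinates are reported with NaN distance, not
    dropped.  Returns the table and the Spearman rank correlation between
    median AMid (similarity) and distance across populations with known
    distances.
    """
    norm = profiles_to_frame(profiles, "normalized")
    if target_population not in norm.columns:
        raise ValueError(f"{target_population!r} is not a panel population")
    pops = metadata.loc[norm.index, "population"]
    has_coords = {"latitude", "longitude"}.issubset(metadata.columns)

    def pop_point(pop: str) -> GeoPoint | None:
        if not has_coords:
            return None
        rows = metadata[metadata["population"] == pop][["latitude", "longitude"]].dropna()
        if rows.empty:
            return None
        return GeoPoint(rows["latitude"].mean(), rows["longitude"].mean())

    target_point = pop_point(target_population)
    records = []
    for pop in pops.drop_duplicates():
        median_amid = float(norm.loc[pops == pop, target_population].median())
        if route_distances is not None and pop in route_distances:
            km = float(route_distances[pop])
        else:
            point = pop_point(pop)
            if point is None or target_point is None:
                km = np.nan
            else:
                km = great_circle_km(point, target_point)
        records.append({"population": pop, "median_amid": median_amid,
                        "distance_km": km})
    table = pd.DataFrame(records).set_index("population")
    known = table.dropna(subset=["distance_km"])
    rho = float(spearmanr(known["median_amid"], known["distance_km"]).statistic) \
        if len(known) >= 3 else float("nan")
    return table, rho
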