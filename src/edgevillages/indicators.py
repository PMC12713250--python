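"""Village-level indicator system: cohesion, capacity, travel time.

Twelve representative indicators describe each village, split into an
*active mobility* group (travel time, facility service capacity,
cross-county healthcare-seeking: attributes of deliberate choice) and a
*passive mobility* group (population size, village classification, age
structure, ethnic composition, road distance, bus frequency, elevation,
slope, cohesion: supply-shortfall context the village cannot choose).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIVE_INDICATORS",
    "PASSIVE_INDICATORS",
    "cohesion_index",
    "capacity_score",
    "travel_time",
    "population_weighted_centroid",
    "bus_covered",
    "assemble_indicators",
]

ACTIVE_INDICATORS = ("travel_time", "capacity", "cross_county")
PASSIVE_INDICATORS = ("population", "village_class", "age_structure",
                      "ethnic_share", "road_distance", "bus_frequency",
                      "elevation", "slope", "cohesion")


def cohesion_index(patches) -> float:
    """Patch-cohesion index of a village's building footprint.

        COHESION = (1 - sum_j P_j / sum_j P_j sqrt(a_j))
                   * (1 - 1 / sqrt(A))^(-1)

    with P_j the perimeter and a_j the area of building patch j, and A
    the total building coverage area.  Large, compact patches push the
    index toward 1 (clustered settlement); many small patches push it
    down.  The value is reported raw -- the printed formula does not
    itself enforce the nominal [-1, 1] range -- with a warning outside
    that range.
    """
    P = np.asarray([p for p, _ in patches.patches], dtype=float)
    a = np.asarray([av for _, av in patches.patches], dtype=float)
    A = float(patches.total_area)
    if (a <= 0).any():
        raise ValueError("patch areas must be positive")
    if A <= 1.0:
        raise ValueError("total building coverage area A must exceed 1 "
                         "(the (1 - 1/sqrt(A))^-1 term blows up)")
    value = (1.0 - P.sum() / (P * np.sqrt(a)).sum()) / (1.0 - 1.0 / math.sqrt(A))
    if not -1.0 <= value <= 1.0:
        logger.warning("cohesion index %.4f outside the nominal [-1, 1] range",
                       value)
    return float(value)


def capacity_score(facility_table: pd.DataFrame,
                   sign_column: str = "n_physicians") -> pd.Series:
    """First-principal-factor score of facility capacity indicators.

    Columns (e.g. total wage expenditure and counts of practicing
    physicians, nurses and health technicians) are standardized,
    zero-variance columns are dropped with a warning, and the first
    principal factor is extracted; the loading vector is sign-fixed so
    the ``sign_column`` loading is positive.  Scores are returned with
    zero mean and unit variance.
    """
    X = facility_table.select_dtypes(include=[np.number]).astype(float)
    if len(X) < 2:
        raise ValueError("capacity_score needs at least 2 facilities")
    keep = []
    for c in X.columns:
        if X[c].std(ddof=0) > 0:
            keep.append(c)
        else:
            logger.warning("capacity_score: dropping zero-variance column %r", c)
    if len(keep) < 2:
        raise ValueError("capacity_score needs >= 2 indicator columns with "
                         "nonzero variance")
    Z = (X[keep] - X[keep].mean()) / X[keep].std(ddof=0)
    _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loading = vt[0]
    if sign_column in keep:
        anchor = keep.index(sign_column)
    else:
        anchor = 0
    if loading[anchor] < 0:
        loading = -loading
    scores = Z.to_numpy() @ loading
    sd = scores.std(ddof=0)
    if sd > 0:
        scores = scores / sd
    return pd.Series(scores, index=facility_table.index, name="capacity")


def travel_time(village=None, facility=None, mode: str = "synthetic",
                terrain_multiplier: float = 1.0, speed_kmh: float = 40.0,
                access_penalty_s: float = 60.0,
                table: pd.DataFrame | None = None,
                origin: str | None = None, destination: str | None = None,
                mad_factor: float = 3.0) -> float:
    """Travel time in seconds between a village and a facility.

    ``synthetic`` mode converts the Euclidean distance between the
    population-weighted centroids into driving seconds via a terrain
    multiplier, plus a fixed access penalty (symmetric by construction).
    ``table`` mode averages repeated timestamped measurements for the
    (origin, destination) pair after dropping outliers more than
    ``mad_factor`` median-absolute-deviations from the median.
    """
    if mode == "synthetic":
        (x1, y1) = village.centroid if hasattr(village, "centroid") else village
        (x2, y2) = facility.location if hasattr(facility, "location") else facility
        dist = math.hypot(x1 - x2, y1 - y2)
        return dist / speed_kmh * 3600.0 * terrain_multiplier + access_penalty_s
    if mode == "table":
        if table is None:
            raise ValueError("table mode requires a travel-time table")
        sel = table[(table["origin"] == origin)
                    & (table["destination"] == destination)]
        if sel.empty:
            raise KeyError(f"no travel-time rows for ({origin!r}, {destination!r})")
        vals = sel["seconds"].to_numpy(float)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad > 0:
            vals = vals[np.abs(vals - med) <= mad_factor * mad]
        return float(vals.mean())
    raise ValueError("mode must be 'synthetic' or 'table'")


def population_weighted_centroid(points) -> tuple[float, float]:
    """Coordinate-wise weighted mean of ((x, y), weight) pairs."""
    coords = np.asarray([c for c, _ in points], dtype=float)
    w = np.asarray([wt for _, wt in points], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    c = (coords * w[:, None]).sum(axis=0) / w.sum()
    return float(c[0]), float(c[1])


def bus_covered(village_xy, stop_xy, walking_speed_kmh: float = 4.5,
                minutes: float = 5.0) -> bool:
    """Whether a village lies within a short walk of a bus stop.

    A village within ``minutes`` of walking (default 5 min at 4.5 km/h,
    about 375 m) from any stop counts as covered by the route.
    """
    reach = walking_speed_kmh * minutes / 60.0
    stops = np.atleast_2d(np.asarray(stop_xy, dtype=float))
    d = np.linalg.norm(stops - np.asarray(village_xy, dtype=float), axis=1)
    return bool((d <= reach).any())


def _local_and_cross_candidates(county, capacity: pd.Series):
    """Per village: the own-township reference facility and the best
    cross-township alternative (shortest travel time; the anchor wins
    ties through its scale)."""
    out = {}
    fac = {f.facility_id: f for f in county.facilities}
    for v in county.villages:
        times = county.travel_time_s.loc[v.village_id]
        own = [f for f in county.facilities if f.township_id == v.township_id]
        cross = [f for f in county.facilities if f.township_id != v.township_id]
        if own:
            local = min(own, key=lambda f: times[f.facility_id])
        else:
            in_county = [f for f in cross if f.in_county]
            local = min(in_county or cross, key=lambda f: times[f.facility_id])
        if not cross:
            raise ValueError(f"village {v.village_id}: no cross-region "
                             "candidate facility exists")
        best_cross = min(cross, key=lambda f: times[f.facility_id]
                         - 200.0 * capacity.get(f.facility_id, 0.0))
        out[v.village_id] = (local, best_cross)
    del fac
    return out


def assemble_indicators(county, network=None,
                        edge_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the 12-indicator table, one row per village.

    Active indicators: ``travel_time`` (seconds to the village's
    own-township reference facility), ``capacity`` (that facility's
    factor score) and ``cross_county`` (1 when the village's main
    outflow destination lies outside the county).  Passive indicators
    are the village attributes plus the cohesion index.  Auxiliary
    ``*_cross`` columns carry the cross-region alternative's attributes
    for the choice model.
    """
    fac_df = county.facilities_df()[
        ["wage_expenditure", "n_physicians", "n_nurses", "n_health_technicians"]]
    capacity = capacity_score(fac_df)
    candidates = _local_and_cross_candidates(county, capacity)
    out_townships = {f.township_id for f in county.facilities if not f.in_county}

    rows = []
    for v in county.villages:
        vid = v.village_id
        local, cross = candidates[vid]
        times = county.travel_time_s.loc[vid]
        cross_county = 0
        if network is not None and network.W is not None and vid in network.W.index:
            main_dest = network.W.loc[vid].idxmax()
            cross_county = int(main_dest in out_townships)
        rows.append({
            "village_id": vid,
            "township_id": v.township_id,
            "travel_time": float(times[local.facility_id]),
            "capacity": float(capacity[local.facility_id]),
            "cross_county": cross_county,
            "population": v.population,
            "village_class": v.village_class,
            "age_structure": v.share_aged_60_plus,
            "ethnic_share": v.share_minority,
            "road_distance": v.road_distance,
            "bus_frequency": v.bus_frequency,
            "elevation": v.elevation,
            "slope": v.slope,
            "cohesion": county.cohesion[vid],
            # cross-region alternative attributes for the choice model
            "travel_time_cross": float(times[cross.facility_id]),
            "capacity_cross": float(capacity[cross.facility_id]),
            "cross_county_cross": int(not cross.in_county),
        })
    table = pd.DataFrame(rows).set_index("village_id")
    missing = [c for c in ACTIVE_INDICATORS + PASSIVE_INDICATORS
               if c not in table.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    if edge_table is not None:
        table["is_edge"] = edge_table["is_edge"].reindex(table.index)
    return table
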