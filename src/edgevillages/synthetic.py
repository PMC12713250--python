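"""Synthetic county generator with a known discrete-choice ground truth.

The real study region (a mountainous autonomous county with 7 townships,
~70 administrative villages and 4,314 valid OD healthcare-seeking records)
cannot be redistributed, so this module generates a synthetic county with
the same structure: townships scattered on an abstract plane, villages
placed by seeded Poisson scatter inside township Voronoi cells, facilities
with correlated capacity attributes, one "super-HSA" anchor facility with
extra pull, and OD records simulated from a random-utility logit choice
process with Gumbel errors.

Because the choice process and its parameters are known, every downstream
stage (flow aggregation, community detection, edge-village classification,
feature selection, choice-model estimation) can be validated against
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountyConfig",
    "Village",
    "Facility",
    "PatchSet",
    "County",
    "generate_county",
    "generate_patches",
    "simulate_od_records",
]


@dataclass(frozen=True)
class CountyConfig:
    """Configuration of the synthetic county and its choice process.

    The utility of village ``i`` choosing facility ``f`` is

        V_if = b1 * time_if + b2 * scale_f
               + cross_if * (ASC + b3*cohesion_i + b4*class_i
                             + b5*population_i + b6*minority_i)
               + super_hsa_pull * anchor_f

    where ``cross_if`` indicates that ``f`` lies outside ``i``'s own
    administrative township, and the chosen alternative maximizes
    ``V_if + noise_scale * Gumbel(0, 1)``.  ``true_beta`` holds
    (b1..b6); the defaults are the study's published point estimates for
    (travel time [s], capacity scale, cohesion, village class,
    population, minority share) and the alternative-specific constant.
    """

    n_townships: int = 7
    villages_per_township: tuple[int, int] = (8, 12)
    n_respondents: int = 4314
    super_hsa_pull: float = 3.0
    true_beta: tuple[float, ...] = (
        -0.0033925,   # travel time, per second
        0.0054233,    # facility capacity scale
        33.47307,     # cohesion index
        -1.420579,    # village classification (1..3)
        0.0002493,    # population size, persons
        4.166709,     # minority population share
    )
    asc_true: float = -27.25859
    noise_scale: float = 1.0
    seed: int = 0
    # geometry and plumbing
    county_size_km: float = 60.0
    n_outside_facilities: int = 1
    facility_count_probs: tuple[float, float, float] = (0.1, 0.7, 0.2)
    speed_kmh: float = 40.0
    access_penalty_s: float = 60.0
    patch_clustering: float = 0.7

    def __post_init__(self) -> None:
        if self.n_townships < 2:
            raise ValueError(
                "n_townships must be >= 2: edge villages are undefined "
                "without an administrative boundary"
            )
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        lo, hi = self.villages_per_township
        if lo < 1 or hi < lo:
            raise ValueError("villages_per_township must be a positive range")
        if len(self.true_beta) != 6:
            raise ValueError("true_beta must have 6 entries")


@dataclass
class Village:
    village_id: str
    township_id: str
    centroid: tuple[float, float]          # planar km
    population: int
    share_aged_60_plus: float
    share_minority: float
    village_class: int                     # 3 = excellent, 2 = good, 1 = poor
    road_distance: float                   # km to national/provincial road
    bus_frequency: float                   # services per day
    elevation: float                       # m
    slope: float                           # degrees

    def __post_init__(self) -> None:
        if not 0.0 <= self.share_aged_60_plus <= 1.0:
            raise ValueError(f"{self.village_id}: share_aged_60_plus not in [0,1]")
        if not 0.0 <= self.share_minority <= 1.0:
            raise ValueError(f"{self.village_id}: share_minority not in [0,1]")
        if self.village_class not in (1, 2, 3):
            raise ValueError(f"{self.village_id}: village_class must be 1, 2 or 3")
        if self.population < 0 or self.road_distance < 0:
            raise ValueError(f"{self.village_id}: negative population/road_distance")


@dataclass
class Facility:
    facility_id: str
    township_id: str
    location: tuple[float, float]          # planar km
    wage_expenditure: float
    n_physicians: int
    n_nurses: int
    n_health_technicians: int
    scale: float = 0.0                     # latent capacity scale used by the DGP
    in_county: bool = True
    is_anchor: bool = False

    def __post_init__(self) -> None:
        if min(self.n_physicians, self.n_nurses, self.n_health_technicians) < 0:
            raise ValueError(f"{self.facility_id}: staff counts must be >= 0")


@dataclass
class PatchSet:
    """Building patches of one village: (perimeter P_j [m], area a_j [m^2])."""

    patches: list[tuple[float, float]]
    total_area: float                      # A, total building coverage area [m^2]

    def __post_init__(self) -> None:
        if not self.patches:
            raise ValueError("PatchSet needs at least one patch")
        for p, a in self.patches:
            if a <= 0 or p <= 0:
                raise ValueError("patch perimeter and area must be positive")
        if self.total_area < max(a for _, a in self.patches):
            raise ValueError("total_area must be >= the largest patch area")


@dataclass
class County:
    config: CountyConfig
    villages: list[Village]
    facilities: list[Facility]
    townships: list[str]
    travel_time_s: pd.DataFrame            # villages x facilities, seconds
    patch_sets: dict[str, PatchSet]
    cohesion: dict[str, float]
    truth: dict = field(default_factory=dict)

    @property
    def anchor_facility_id(self) -> str | None:
        for f in self.facilities:
            if f.is_anchor:
                return f.facility_id
        return None

    def villages_df(self) -> pd.DataFrame:
        rows = []
        for v in self.villages:
            rows.append({
                "village_id": v.village_id,
                "township_id": v.township_id,
                "x_km": v.centroid[0],
                "y_km": v.centroid[1],
                "population": v.population,
                "share_aged_60_plus": v.share_aged_60_plus,
                "share_minority": v.share_minority,
                "village_class": v.village_class,
                "road_distance": v.road_distance,
                "bus_frequency": v.bus_frequency,
                "elevation": v.elevation,
                "slope": v.slope,
                "cohesion": self.cohesion.get(v.village_id, np.nan),
            })
        return pd.DataFrame(rows).set_index("village_id")

    def facilities_df(self) -> pd.DataFrame:
        rows = []
        for f in self.facilities:
            rows.append({
                "facility_id": f.facility_id,
                "township_id": f.township_id,
                "x_km": f.location[0],
                "y_km": f.location[1],
                "wage_expenditure": f.wage_expenditure,
                "n_physicians": f.n_physicians,
                "n_nurses": f.n_nurses,
                "n_health_technicians": f.n_health_technicians,
                "scale": f.scale,
                "in_county": f.in_county,
                "is_anchor": f.is_anchor,
            })
        return pd.DataFrame(rows).set_index("facility_id")

    def systematic_utilities(self) -> pd.DataFrame:
        """Deterministic utility V_if for every village-facility pair."""
        cfg = self.config
        b1, b2, b3, b4, b5, b6 = cfg.true_beta
        fac_ids = [f.facility_id for f in self.facilities]
        rows = {}
        for v in self.villages:
            t = self.travel_time_s.loc[v.village_id, fac_ids].to_numpy(float)
            coh = self.cohesion[v.village_id]
            case_term = (cfg.asc_true + b3 * coh + b4 * v.village_class
                         + b5 * v.population + b6 * v.share_minority)
            util = np.empty(len(fac_ids))
            for k, f in enumerate(self.facilities):
                u = b1 * t[k] + b2 * f.scale
                if f.township_id != v.township_id:
                    u += case_term
                if f.is_anchor:
                    u += cfg.super_hsa_pull
                util[k] = u
            rows[v.village_id] = util
        return pd.DataFrame.from_dict(rows, orient="index", columns=fac_ids)

    def choice_probabilities(self) -> pd.DataFrame:
        """Exact logit choice probabilities over facilities per village."""
        v = self.systematic_utilities() / self.config.noise_scale
        e = np.exp(v.to_numpy() - v.to_numpy().max(axis=1, keepdims=True))
        return pd.DataFrame(e / e.sum(axis=1, keepdims=True),
                            index=v.index, columns=v.columns)

    def facility_township(self) -> dict[str, str]:
        return {f.facility_id: f.township_id for f in self.facilities}


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = min(sd * sd, mean * (1.0 - mean) * 0.999)
    nu = mean * (1.0 - mean) / var - 1.0
    return max(mean * nu, 0.05), max((1.0 - mean) * nu, 0.05)


def generate_patches(village: Village, seed: int,
                     clustering: float = 0.7) -> PatchSet:
    """Generate the building-patch geometry of one village.

    ``clustering`` in (0, 1] controls how aggregated the built footprint
    is: higher values merge the per-capita building stock into fewer,
    larger patches, which raises the cohesion index; ``clustering=1``
    yields a single square patch.  Deterministic under ``seed``.
    """
    if not 0.0 < clustering <= 1.0:
        raise ValueError("clustering must be in (0, 1]")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7])
    total_built = max(400.0, village.population * 30.0)   # m^2, ~30 m^2/person
    footprint = total_built / 0.15                        # 15% built fraction
    if clustering == 1.0:
        side = math.sqrt(total_built)
        return PatchSet(patches=[(4.0 * side, total_built)],
                        total_area=footprint)
    m = max(1, int(round((1.0 - clustering) * village.population / 2.5)))
    shares = rng.dirichlet(np.full(m, 2.0))
    areas = np.maximum(shares * total_built, 4.0)
    aspect = rng.uniform(1.0, 2.5, size=m)
    perims = 2.0 * (np.sqrt(areas * aspect) + np.sqrt(areas / aspect))
    return PatchSet(patches=list(zip(perims.tolist(), areas.tolist())),
                    total_area=footprint)


def _place_townships(rng: np.random.Generator, n: int, size: float) -> np.ndarray:
    # spread seeds with a best-candidate heuristic for roughly even cells
    pts = [rng.uniform(0.2 * size, 0.8 * size, 2)]
    while len(pts) < n:
        cands = rng.uniform(0.1 * size, 0.9 * size, (32, 2))
        d = np.min(np.linalg.norm(
            cands[:, None, :] - np.asarray(pts)[None, :, :], axis=2), axis=1)
        pts.append(cands[int(np.argmax(d))])
    return np.asarray(pts)


def _scatter_villages(rng: np.random.Generator, seeds: np.ndarray,
                      quotas: np.ndarray, size: float) -> list[tuple[int, np.ndarray]]:
    """Poisson scatter inside township Voronoi cells (nearest-seed membership)."""
    remaining = quotas.copy()
    placed: list[tuple[int, np.ndarray]] = []
    attempts = 0
    while remaining.sum() > 0 and attempts < 200:
        pts = rng.uniform(0.0, size, (int(remaining.sum()) * 8, 2))
        owner = np.argmin(np.linalg.norm(
            pts[:, None, :] - seeds[None, :, :], axis=2), axis=1)
        for p, o in zip(pts, owner):
            if remaining[o] > 0:
                placed.append((int(o), p))
                remaining[o] -= 1
        attempts += 1
    for t in np.nonzero(remaining)[0]:       # fallback: jitter around the seed
        for _ in range(int(remaining[t])):
            placed.append((int(t), seeds[t] + rng.normal(0, 0.05 * size, 2)))
    return placed


def generate_county(config: CountyConfig) -> County:
    """Generate a full synthetic county; bit-identical under the same seed."""
    cfg = config
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0])
    L = cfg.county_size_km
    seeds = _place_townships(rng, cfg.n_townships, L)
    townships = [f"T{i + 1}" for i in range(cfg.n_townships)]

    lo, hi = cfg.villages_per_township
    quotas = rng.integers(lo, hi + 1, cfg.n_townships)
    placed = _scatter_villages(rng, seeds, quotas, L)
    placed.sort(key=lambda t: (t[0], t[1][0], t[1][1]))

    villages: list[Village] = []
    a60_a, a60_b = _beta_params(0.18, 0.05)
    min_a, min_b = _beta_params(0.606, 0.413)
    for k, (tw, pt) in enumerate(placed):
        pop = int(np.clip(rng.lognormal(7.114, 0.932), 50, 25000))
        elev = float(rng.uniform(200, 1000))
        villages.append(Village(
            village_id=f"V{k + 1:03d}",
            township_id=townships[tw],
            centroid=(float(pt[0]), float(pt[1])),
            population=pop,
            share_aged_60_plus=float(rng.beta(a60_a, a60_b)),
            share_minority=float(rng.beta(min_a, min_b)),
            village_class=int(rng.choice([1, 2, 3], p=[0.25, 0.30, 0.45])),
            road_distance=float(rng.lognormal(0.8, 0.7)),
            bus_frequency=float(rng.poisson(4)),
            elevation=elev,
            slope=float(np.clip(rng.normal(8 + elev / 100, 4), 0.5, 35)),
        ))

    # facilities: each in-county township hosts 0-2; at least one overall
    facilities: list[Facility] = []
    counts = rng.choice([0, 1, 2], size=cfg.n_townships,
                        p=list(cfg.facility_count_probs))
    if counts.sum() == 0:
        counts[0] = 1
    fid = 0
    for t, c in enumerate(counts):
        for _ in range(int(c)):
            fid += 1
            scale = float(np.clip(rng.normal(1387, 251), 600, 2600))
            loc = seeds[t] + rng.normal(0, 0.03 * L, 2)
            facilities.append(_make_facility(
                rng, f"F{fid:02d}", townships[t], loc, scale, in_county=True))
    for k in range(cfg.n_outside_facilities):
        fid += 1
        # a county-level hospital just beyond the border, larger than average
        scale = float(np.clip(rng.normal(1900, 150), 1500, 2800))
        edge = rng.integers(0, 4)
        loc = rng.uniform(0.2 * L, 0.8 * L, 2)
        loc[edge % 2] = -0.05 * L if edge < 2 else 1.05 * L
        facilities.append(_make_facility(
            rng, f"F{fid:02d}", f"OUT{k + 1}", loc, scale, in_county=False))

    if cfg.super_hsa_pull > 0:
        in_county = [f for f in facilities if f.in_county]
        anchor = max(in_county, key=lambda f: f.scale)
        anchor.is_anchor = True

    # travel times: Euclidean distance x seeded terrain multiplier
    vxy = np.asarray([v.centroid for v in villages])
    fxy = np.asarray([f.location for f in facilities])
    dist = np.linalg.norm(vxy[:, None, :] - fxy[None, :, :], axis=2)
    mult = rng.lognormal(0.0, 0.15, size=dist.shape)
    time_s = dist / cfg.speed_kmh * 3600.0 * mult + cfg.access_penalty_s
    travel = pd.DataFrame(time_s,
                          index=[v.village_id for v in villages],
                          columns=[f.facility_id for f in facilities])

    patch_sets = {}
    cohesion = {}
    from edgevillages.indicators import cohesion_index
    for k, v in enumerate(villages):
        ps = generate_patches(v, seed=cfg.seed * 1000 + k,
                              clustering=cfg.patch_clustering)
        patch_sets[v.village_id] = ps
        cohesion[v.village_id] = cohesion_index(ps)

    county = County(config=cfg, villages=villages, facilities=facilities,
                    townships=townships, travel_time_s=travel,
                    patch_sets=patch_sets, cohesion=cohesion)
    county.truth = _ground_truth(county)
    return county


def _make_facility(rng: np.random.Generator, fid: str, township: str,
                   loc: np.ndarray, scale: float, in_county: bool) -> Facility:
    return Facility(
        facility_id=fid,
        township_id=township,
        location=(float(loc[0]), float(loc[1])),
        wage_expenditure=float(scale * 3000 * rng.lognormal(0, 0.1)),
        n_physicians=int(max(1, round(scale / 60 + rng.normal(0, 2)))),
        n_nurses=int(max(1, round(scale / 50 + rng.normal(0, 2)))),
        n_health_technicians=int(max(0, round(scale / 80 + rng.normal(0, 2)))),
        scale=scale,
        in_county=in_county,
    )


def _ground_truth(county: County) -> dict:
    """Exact-probability labels for the planted structure.

    A village's *functional township* is the township receiving the
    largest expected flow share under the true choice probabilities.  A
    village is a true edge village when (a) its functional township
    differs from its administrative township, (b) more than half of its
    expected outflow leaves the administrative township, and (c) the
    administrative township is still "anchored" -- at least one of its
    own villages keeps it as functional township -- so that a
    community-detection delineation can represent the administrative
    reference at all.
    """
    probs = county.choice_probabilities()
    fac_tw = county.facility_township()
    share = probs.T.groupby(fac_tw).sum().T    # villages x townships
    functional = share.idxmax(axis=1)
    cross = {}
    for v in county.villages:
        own = share.loc[v.village_id].get(v.township_id, 0.0)
        cross[v.village_id] = 1.0 - float(own)
    # administrative reference township, mirroring the delineation rule:
    # a township with a facility that keeps at least one loyal village is
    # its own reference; otherwise the modal functional township of its
    # member villages stands in (ties -> lowest township id)
    loyal = {t: False for t in county.townships}
    for v in county.villages:
        if functional[v.village_id] == v.township_id:
            loyal[v.township_id] = True
    has_facility = {t: False for t in county.townships}
    for f in county.facilities:
        if f.township_id in has_facility:
            has_facility[f.township_id] = True
    reference = {}
    for t in county.townships:
        if has_facility[t] and loyal[t]:
            reference[t] = t
        else:
            fs = [functional[v.village_id] for v in county.villages
                  if v.township_id == t]
            if fs:
                counts = pd.Series(fs).value_counts()
                reference[t] = counts[counts == counts.max()].index.min()
            else:
                reference[t] = t
    is_edge = {}
    for v in county.villages:
        is_edge[v.village_id] = bool(
            functional[v.village_id] != reference[v.township_id]
            and cross[v.village_id] > 0.5
        )
    return {
        "functional_township": functional.to_dict(),
        "cross_share": cross,
        "is_edge": is_edge,
        "anchor_facility": county.anchor_facility_id,
        "true_beta": list(county.config.true_beta),
        "asc_true": county.config.asc_true,
    }


def simulate_od_records(county: County, config: CountyConfig | None = None):
    """Simulate OD healthcare-seeking records from the logit choice process.

    Each respondent draws a residential village proportional to population
    and a destination facility from the village's logit choice
    probabilities.  Returns ``n_respondents`` records with schema
    (respondent_id, origin_village, dest_facility).
    """
    from edgevillages.flows import ODRecord

    cfg = config or county.config
    if not county.villages or not county.facilities:
        raise ValueError("cannot simulate OD records for an empty county")
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1])
    pops = np.asarray([v.population for v in county.villages], float)
    if pops.sum() <= 0:
        raise ValueError("county has no population")
    origin_idx = rng.choice(len(county.villages), size=cfg.n_respondents,
                            p=pops / pops.sum())
    probs = county.choice_probabilities()
    fac_ids = list(probs.columns)
    # destinations drawn in one batch per village (deterministic: villages
    # visited in index order, respondents within a village in record order)
    dest_idx = np.empty(cfg.n_respondents, dtype=int)
    for oi in range(len(county.villages)):
        rows = np.flatnonzero(origin_idx == oi)
        if len(rows) == 0:
            continue
        p = probs.loc[county.villages[oi].village_id].to_numpy()
        dest_idx[rows] = rng.choice(len(fac_ids), size=len(rows), p=p)
    return [
        ODRecord(respondent_id=f"R{r + 1:05d}",
                 origin_village=county.villages[origin_idx[r]].village_id,
                 dest_facility=fac_ids[dest_idx[r]])
        for r in range(cfg.n_respondents)
    ]
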