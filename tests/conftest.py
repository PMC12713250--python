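import networkx as nx
import numpy as np
import pandas as pd
import pytest

from edgevillages import (
    County,
    CountyConfig,
    Facility,
    Village,
    aggregate_flows,
    build_graph,
    delineate_hsas,
    generate_county,
    identify_edge_villages,
    louvain,
    normalize_weights,
    postprocess_unassigned,
    simulate_od_records,
)

# County with strong, decisive planted misalignment and low choice noise:
# a very steep distance decay keeps choice margins crisp (no ambiguous
# villages), the anchor's pull reaches ~5 km across township borders, and
# every township hosts exactly one facility.
PLANTED_KWARGS = dict(
    noise_scale=0.05,
    super_hsa_pull=18.0,
    true_beta=(-0.02, 0.0, 0.0, 0.0, 0.0, 0.0),
    asc_true=-8.0,
    n_respondents=20000,
    villages_per_township=(6, 8),
    facility_count_probs=(0.0, 1.0, 0.0),
)


def planted_config(seed: int) -> CountyConfig:
    return CountyConfig(seed=seed, **PLANTED_KWARGS)


def planted_edge_run(seed: int, share_threshold: float = 0.5):
    """Full chain on a planted county: returns (edge table, truth set)."""
    county = generate_county(planted_config(seed))
    records = simulate_od_records(county)
    network = normalize_weights(
        aggregate_flows(records, county.facility_township(), min_records=1))
    result = louvain(build_graph(network), seed=seed)
    delineation = postprocess_unassigned(
        delineate_hsas(result.final, county), network=network, county=county)
    table = identify_edge_villages(delineation, network, county,
                                   share_threshold=share_threshold)
    truth = {v for v, b in county.truth["is_edge"].items() if b}
    return table, truth


def toy_choice_county(times=(600.0, 600.0), scales=(0.0, 0.0),
                      beta_scale=0.0, asc=0.0, n_respondents=10000,
                      seed=0) -> County:
    """One village, two cross-township facilities with controlled utilities."""
    cfg = CountyConfig(
        seed=seed, n_respondents=n_respondents,
        true_beta=(0.0, beta_scale, 0.0, 0.0, 0.0, 0.0),
        asc_true=asc, super_hsa_pull=0.0,
    )
    village = Village("V1", "T1", (0.0, 0.0), 1000, 0.2, 0.5, 2,
                      1.0, 4.0, 500.0, 10.0)
    facilities = [
        Facility("F1", "T2", (1.0, 0.0), 1e6, 10, 10, 5, scale=scales[0]),
        Facility("F2", "T3", (2.0, 0.0), 1e6, 10, 10, 5, scale=scales[1]),
    ]
    travel = pd.DataFrame([[times[0], times[1]]], index=["V1"],
                          columns=["F1", "F2"])
    return County(config=cfg, villages=[village], facilities=facilities,
                  townships=["T1", "T2", "T3"], travel_time_s=travel,
                  patch_sets={}, cohesion={"V1": 0.8})


def random_weighted_graph(seed: int, n_max: int = 10) -> nx.Graph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                g.add_edge(i, j, weight=float(rng.uniform(0.1, 2.0)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1, weight=1.0)
    return g


def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                               (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)])
    return g


@pytest.fixture(scope="session")
def default_county() -> County:
    return generate_county(CountyConfig(seed=11))


@pytest.fixture(scope="session")
def default_chain(default_county):
    """records -> network -> partition -> delineation -> edge table."""
    county = default_county
    records = simulate_od_records(county)
    network = normalize_weights(
        aggregate_flows(records, county.facility_township(), min_records=10))
    result = louvain(build_graph(network), seed=11)
    delineation = postprocess_unassigned(
        delineate_hsas(result.final, county), network=aggregate_flows(
            records, county.facility_township(), min_records=1),
        county=county)
    edge_table = identify_edge_villages(delineation, network, county)
    return {"county": county, "records": records, "network": network,
            "louvain": result, "delineation": delineation,
            "edge_table": edge_table}
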