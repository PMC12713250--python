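"""Tests of HSA delineation, post-processing rules and edge villages."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from edgevillages import (
    County,
    CountyConfig,
    Facility,
    Partition,
    Village,
    aggregate_flows,
    delineate_hsas,
    identify_edge_villages,
    normalize_weights,
    postprocess_unassigned,
)
from edgevillages.flows import ODRecord

from conftest import planted_edge_run


def _village(vid, township, pop=100):
    return Village(vid, township, (0.0, 0.0), pop, 0.2, 0.5, 2,
                   1.0, 4.0, 500.0, 10.0)


def _county(villages, facilities, townships):
    travel = pd.DataFrame(
        600.0, index=[v.village_id for v in villages],
        columns=[f.facility_id for f in facilities])
    return County(config=CountyConfig(seed=0), villages=villages,
                  facilities=facilities, townships=townships,
                  travel_time_s=travel, patch_sets={},
                  cohesion={v.village_id: 0.8 for v in villages})


@pytest.fixture
def small_setup():
    villages = [_village("V1", "T1", 100), _village("V2", "T1", 200),
                _village("V3", "T2", 300)]
    facilities = [Facility("F1", "T1", (0, 0), 1e6, 10, 10, 5),
                  Facility("F2", "T2", (1, 0), 1e6, 10, 10, 5,
                           in_county=False)]
    county = _county(villages, facilities, ["T1", "T2"])
    partition = Partition(assignment={"V1": 0, "V2": 0, "T1": 0,
                                      "V3": 1, "T2": 1},
                          modularity=0.4)
    return county, partition


class TestDelineate:
    def test_community_count_and_population_additivity(self, small_setup):
        county, partition = small_setup
        d = delineate_hsas(partition, county)
        assert d.n_hsas == 2
        pops = {h: m["population"] for h, m in d.members.items()}
        assert sorted(pops.values()) == [300, 300]

    def test_out_of_county_only_providers_reported_as_none(self, small_setup):
        county, partition = small_setup
        d = delineate_hsas(partition, county)
        row = d.summary().loc[d.village_hsa["V3"]]
        assert row["providers_within_county"] == "None"
        assert "F2" in row["providers_outside_county"]

    def test_super_hsa_is_largest_population(self, small_setup):
        county, partition = small_setup
        d = delineate_hsas(partition, county)
        pops = {h: m["population"] for h, m in d.members.items()}
        assert d.super_hsa_id == max(pops, key=pops.get)

    def test_villages_outside_partition_listed_unassigned(self, small_setup):
        county, partition = small_setup
        del partition.assignment["V2"]
        d = delineate_hsas(partition, county)
        assert d.unassigned == ["V2"]


class TestPostprocess:
    def _delineation(self, county, partition):
        return delineate_hsas(partition, county)

    def test_nonresidential_unit_joins_adjacent_hsa(self):
        villages = [_village("V1", "T1"), _village("V2", "T2"),
                    _village("N1", "T1", pop=0)]
        facilities = [Facility("F1", "T1", (0, 0), 1e6, 10, 10, 5),
                      Facility("F2", "T2", (1, 0), 1e6, 10, 10, 5)]
        county = _county(villages, facilities, ["T1", "T2"])
        partition = Partition({"V1": 0, "T1": 0, "V2": 1, "T2": 1}, 0.3)
        adjacency = nx.Graph([("N1", "V2")])
        d = postprocess_unassigned(self._delineation(county, partition),
                                   adjacency=adjacency, county=county)
        assert d.village_hsa["N1"] == d.village_hsa["V2"]
        assert d.unassigned == []

    def test_sparse_village_follows_majority_flow(self, small_setup):
        county, partition = small_setup
        del partition.assignment["V2"]
        records = ([ODRecord(f"a{i}", "V2", "F1") for i in range(7)]
                   + [ODRecord(f"b{i}", "V2", "F2") for i in range(2)])
        net = aggregate_flows(records, county.facility_township(), 1)
        d = postprocess_unassigned(delineate_hsas(partition, county),
                                   network=net, county=county)
        assert d.village_hsa["V2"] == d.village_hsa["V1"]

    def test_zero_flow_village_uses_aux_assignment(self, small_setup):
        county, partition = small_setup
        del partition.assignment["V2"]
        d0 = delineate_hsas(partition, county)
        target = d0.village_hsa["V3"]
        d = postprocess_unassigned(d0, aux_assignments={"V2": target},
                                   county=county)
        assert d.village_hsa["V2"] == target
        assert ("V2", target, "rule2_aux_assignment") in d.adjustments

    def test_unassignable_unit_is_an_error(self, small_setup):
        county, partition = small_setup
        del partition.assignment["V2"]
        with pytest.raises(ValueError, match="V2"):
            postprocess_unassigned(delineate_hsas(partition, county),
                                   county=county)

    def test_idempotent(self, small_setup):
        county, partition = small_setup
        del partition.assignment["V2"]
        d = postprocess_unassigned(delineate_hsas(partition, county),
                                   aux_assignments={"V2": 1}, county=county)
        before = dict(d.village_hsa)
        d2 = postprocess_unassigned(d, aux_assignments={"V2": 1},
                                    county=county)
        assert d2.village_hsa == before


class TestEdgeVillages:
    def _flows(self, county, spec):
        records = []
        i = 0
        for origin, dest_fac, n in spec:
            for _ in range(n):
                records.append(ODRecord(f"r{i}", origin, dest_fac))
                i += 1
        return normalize_weights(
            aggregate_flows(records, county.facility_township(), 1))

    def test_cross_border_majority_flow_flagged(self, small_setup):
        county, _ = small_setup
        # V2 sends 90% of its flow into T2's differently-labelled community
        partition = Partition({"V1": 0, "T1": 0, "V2": 1, "V3": 1, "T2": 1},
                              0.3)
        net = self._flows(county, [("V1", "F1", 10), ("V3", "F2", 10),
                                   ("V2", "F2", 9), ("V2", "F1", 1)])
        d = delineate_hsas(partition, county)
        table = identify_edge_villages(d, net, county)
        assert table.loc["V2", "is_edge"]
        assert table.loc["V2", "outflow_share"] == pytest.approx(0.9)
        assert table.loc["V2", "main_outflow_destination"] == "T2"
        assert not table.loc["V1", "is_edge"]

    def test_same_hsa_never_flagged_regardless_of_share(self, small_setup):
        county, _ = small_setup
        # V2's community matches its township's, despite cross-border flows
        partition = Partition({"V1": 0, "V2": 0, "T1": 0, "V3": 1, "T2": 1},
                              0.3)
        net = self._flows(county, [("V1", "F1", 10), ("V3", "F2", 10),
                                   ("V2", "F2", 9), ("V2", "F1", 1)])
        table = identify_edge_villages(delineate_hsas(partition, county),
                                       net, county)
        assert not table.loc["V2", "is_edge"]

    def test_all_internal_flows_no_edge_villages(self, small_setup):
        county, partition = small_setup
        net = self._flows(county, [("V1", "F1", 10), ("V2", "F1", 10),
                                   ("V3", "F2", 10)])
        table = identify_edge_villages(delineate_hsas(partition, county),
                                       net, county)
        assert not table["is_edge"].any()

    def test_village_missing_from_delineation_is_an_error(self, small_setup):
        county, partition = small_setup
        del partition.assignment["V2"]
        net = self._flows(county, [("V1", "F1", 10), ("V3", "F2", 10)])
        with pytest.raises(KeyError, match="V2"):
            identify_edge_villages(delineate_hsas(partition, county),
                                   net, county)

    def test_planted_misalignment_recovered(self):
        table, truth = planted_edge_run(seed=101)
        assert set(table.index[table["is_edge"]]) == truth

    def test_threshold_monotonicity(self):
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            table, _ = planted_edge_run(seed=5, share_threshold=thr)
            flagged = set(table.index[table["is_edge"]])
            if prev is not None:
                assert flagged <= prev
            prev = flagged
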