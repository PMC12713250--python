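"""HSA delineation from a partition and edge-village classification.

Communities detected on the healthcare-seeking graph serve as the
preliminary hospital service areas (HSAs).  Two rule-based
post-processing adjustments resolve units the flow data cannot place:
non-residential units are merged into the HSA of an adjacent village,
and villages with sparse flows are assigned to the HSA receiving the
majority of their observed flows (falling back to an auxiliary
expert-knowledge map when no flows exist).

A village is an *edge village* when its functional HSA differs from the
HSA anchored by its own administrative township and the bulk of its
outflow crosses the administrative border.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from edgevillages.community import Partition
from edgevillages.flows import FlowNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "HSADelineation",
    "delineate_hsas",
    "postprocess_unassigned",
    "identify_edge_villages",
]


@dataclass
class HSADelineation:
    """HSAs with their member villages, destination townships and providers."""

    members: dict[int, dict]               # hsa_id -> {villages, townships, ...}
    village_hsa: dict[str, int]            # village -> hsa_id
    township_hsa: dict[str, int]           # destination township node -> hsa_id
    unassigned: list[str] = field(default_factory=list)
    adjustments: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_hsas(self) -> int:
        return len(self.members)

    @property
    def super_hsa_id(self) -> int | None:
        """Descriptive label: the HSA with the largest population."""
        if not self.members:
            return None
        return max(self.members, key=lambda h: self.members[h]["population"])

    def summary(self) -> pd.DataFrame:
        rows = []
        for hsa_id in sorted(self.members):
            m = self.members[hsa_id]
            rows.append({
                "hsa_id": hsa_id,
                "n_villages": len(m["villages"]),
                "population": m["population"],
                "providers_within_county": "; ".join(m["providers_within"]) or "None",
                "providers_outside_county": "; ".join(m["providers_outside"]) or "None",
                "is_super_hsa": hsa_id == self.super_hsa_id,
            })
        return pd.DataFrame(rows).set_index("hsa_id")


def delineate_hsas(partition: Partition, county) -> HSADelineation:
    """Turn a graph partition into an HSA delineation.

    Every community containing at least one village becomes an HSA; its
    population is the sum of member village populations and its provider
    lists are the facilities of member destination townships, split by
    the county-membership flag.  Villages absent from the partition
    (e.g. excluded for sparse flows) are listed as unassigned.
    """
    village_ids = {v.village_id for v in county.villages}
    township_ids = set(county.townships) | {
        f.township_id for f in county.facilities}
    pops = {v.village_id: v.population for v in county.villages}

    by_comm: dict[int, dict] = {}
    for node, comm in partition.assignment.items():
        d = by_comm.setdefault(comm, {"villages": [], "townships": []})
        if node in village_ids:
            d["villages"].append(node)
        elif node in township_ids:
            d["townships"].append(node)
        else:
            logger.warning("partition node %r is neither a village nor a "
                           "destination township", node)

    fac_by_township: dict[str, list] = {}
    for f in county.facilities:
        fac_by_township.setdefault(f.township_id, []).append(f)

    members: dict[int, dict] = {}
    village_hsa: dict[str, int] = {}
    township_hsa: dict[str, int] = {}
    hsa_id = 0
    for comm in sorted(by_comm, key=lambda c: sorted(by_comm[c]["villages"])
                       or sorted(by_comm[c]["townships"])):
        d = by_comm[comm]
        if not d["villages"]:
            continue
        hsa_id += 1
        within, outside = [], []
        for t in sorted(d["townships"]):
            for f in sorted(fac_by_township.get(t, []), key=lambda f: f.facility_id):
                (within if f.in_county else outside).append(f.facility_id)
        members[hsa_id] = {
            "villages": sorted(d["villages"]),
            "townships": sorted(d["townships"]),
            "population": int(sum(pops.get(v, 0) for v in d["villages"])),
            "providers_within": within,
            "providers_outside": outside,
        }
        for v in d["villages"]:
            village_hsa[v] = hsa_id
        for t in d["townships"]:
            township_hsa[t] = hsa_id

    unassigned = sorted(village_ids - set(village_hsa))
    return HSADelineation(members=members, village_hsa=village_hsa,
                          township_hsa=township_hsa, unassigned=unassigned)


def postprocess_unassigned(delineation: HSADelineation,
                           adjacency=None,
                           aux_assignments: dict[str, int] | None = None,
                           network: FlowNetwork | None = None,
                           county=None) -> HSADelineation:
    """Apply the two rule-based adjustments until no unit is unassigned.

    Rule 1 (non-residential units, zero population): merge into the HSA
    of an adjacent assigned village; ties break to the lowest HSA id and
    are logged.  Rule 2 (sparse villages, < min-records flows): assign to
    the HSA receiving the majority of the village's observed flows; when
    no flows exist, fall back to ``aux_assignments`` (the stand-in for
    expert knowledge of predominant care-seeking patterns).  Idempotent.
    """
    aux = aux_assignments or {}
    pops = ({v.village_id: v.population for v in county.villages}
            if county is not None else {})
    still = []
    for unit in list(delineation.unassigned):
        target = None
        rule = None
        if pops.get(unit, 1) == 0 and adjacency is not None and adjacency.has_node(unit):
            hsas = sorted({delineation.village_hsa[nb]
                           for nb in adjacency.neighbors(unit)
                           if nb in delineation.village_hsa})
            if hsas:
                if len(hsas) > 1:
                    logger.warning("unit %s adjacent to several HSAs %s; "
                                   "taking the lowest id", unit, hsas)
                target, rule = hsas[0], "rule1_adjacent"
        if target is None and network is not None and unit in network.D.index:
            row = network.D.loc[unit]
            flows_to_hsa: dict[int, int] = {}
            for t, c in row.items():
                h = delineation.township_hsa.get(t)
                if h is not None and c > 0:
                    flows_to_hsa[h] = flows_to_hsa.get(h, 0) + int(c)
            if flows_to_hsa:
                best = max(flows_to_hsa.values())
                target = min(h for h, c in flows_to_hsa.items() if c == best)
                rule = "rule2_majority_flow"
        if target is None and unit in aux:
            target, rule = int(aux[unit]), "rule2_aux_assignment"
        if target is None:
            still.append(unit)
            continue
        if target not in delineation.members:
            raise ValueError(f"unit {unit!r}: assignment to unknown HSA {target}")
        delineation.members[target]["villages"].append(unit)
        delineation.members[target]["villages"].sort()
        delineation.members[target]["population"] += int(pops.get(unit, 0))
        delineation.village_hsa[unit] = target
        delineation.adjustments.append((unit, target, rule))
    if still:
        raise ValueError(
            "units remain unassignable (no adjacency, no flows, no auxiliary "
            f"assignment): {still}")
    delineation.unassigned = []
    return delineation


def identify_edge_villages(delineation: HSADelineation,
                           network: FlowNetwork,
                           county,
                           share_threshold: float = 0.5) -> pd.DataFrame:
    """Classify edge villages and report their main outflow destinations.

    Village ``v`` is an edge village iff (a) the HSA containing ``v``
    differs from the HSA of its administrative township's destination
    node (for townships without a destination node in the partition --
    e.g. facility-less townships -- the modal HSA of the township's
    villages is the administrative reference), and (b) the share of
    ``v``'s outflow leaving its administrative township exceeds
    ``share_threshold``.  Villages without flow data keep condition (b)
    false and a missing outflow share.
    """
    if network.W is None:
        raise ValueError("normalize_weights must run before edge-village "
                         "identification")
    township_of = {v.village_id: v.township_id for v in county.villages}

    # administrative reference HSA per township
    ref_hsa: dict[str, int | None] = {}
    for t in county.townships:
        if t in delineation.township_hsa:
            ref_hsa[t] = delineation.township_hsa[t]
        else:
            member_hsas = [delineation.village_hsa[v.village_id]
                           for v in county.villages
                           if v.township_id == t
                           and v.village_id in delineation.village_hsa]
            if member_hsas:
                counts = pd.Series(member_hsas).value_counts()
                top = counts[counts == counts.max()].index.min()
                ref_hsa[t] = int(top)
            else:
                ref_hsa[t] = None

    rows = []
    for v in county.villages:
        vid = v.village_id
        if vid not in delineation.village_hsa:
            raise KeyError(f"village {vid!r} missing from the delineation; "
                           "run postprocess_unassigned first")
        hsa = delineation.village_hsa[vid]
        if vid in network.W.index:
            w = network.W.loc[vid]
            main_dest = w.idxmax()        # ties -> first (lowest) label
            outflow_share = float(w.max())
            cross_share = float(1.0 - w.get(v.township_id, 0.0))
        else:
            main_dest, outflow_share, cross_share = None, float("nan"), None
        ref = ref_hsa.get(v.township_id)
        cond_a = ref is not None and hsa != ref
        cond_b = cross_share is not None and cross_share > share_threshold
        rows.append({
            "village_id": vid,
            "township_id": township_of[vid],
            "hsa_id": hsa,
            "is_edge": bool(cond_a and cond_b),
            "main_outflow_destination": main_dest,
            "outflow_share": outflow_share,
            "cross_township_share": cross_share if cross_share is not None
            else float("nan"),
        })
    return pd.DataFrame(rows).set_index("village_id")
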