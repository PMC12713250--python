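"""OD flow aggregation, weight normalization and NCOL graph I/O.

Respondent-level origin-destination records (residential village ->
facility) are mapped to the destination facility's township, aggregated
into per-origin flow counts D_ij, filtered by the minimum-record rule
(origins with fewer than 10 records are excluded by default), and
row-normalized into outflow proportions W_ij = D_ij / sum_j D_ij, which
serve as edge weights of the healthcare-seeking graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ODRecord",
    "FlowNetwork",
    "aggregate_flows",
    "normalize_weights",
    "build_graph",
    "write_ncol",
    "read_ncol",
    "read_od_csv",
    "write_od_csv",
    "apply_merge_map",
]


@dataclass(frozen=True)
class ODRecord:
    """One respondent's (actual or intended) healthcare-seeking flow."""

    respondent_id: str
    origin_village: str
    dest_facility: str

    def __post_init__(self) -> None:
        if not self.respondent_id or not self.origin_village or not self.dest_facility:
            raise ValueError("ODRecord identifiers must be non-empty")


@dataclass
class FlowNetwork:
    """Aggregated flow counts and normalized weights.

    ``D`` holds integer flow counts (origins x destination townships),
    ``W`` the row-normalized proportions (rows of retained origins sum to
    one).  ``excluded_origins`` lists origins dropped by the
    minimum-record rule with the reason.
    """

    D: pd.DataFrame
    W: pd.DataFrame | None = None
    excluded_origins: list[tuple[str, str]] = field(default_factory=list)
    min_records: int = 10

    @property
    def origins(self) -> list[str]:
        return list(self.D.index)

    @property
    def destinations(self) -> list[str]:
        return list(self.D.columns)


def apply_merge_map(records: list[ODRecord],
                    merge_map: dict[str, str]) -> list[ODRecord]:
    """Merge small communities into neighbouring administrative villages.

    The merge map (old origin id -> new origin id) is user-supplied; no
    merging rule is inferred from the data.
    """
    if not merge_map:
        return list(records)
    return [
        ODRecord(r.respondent_id, merge_map.get(r.origin_village, r.origin_village),
                 r.dest_facility)
        for r in records
    ]


def aggregate_flows(records: list[ODRecord],
                    facility_table: dict[str, str] | pd.DataFrame,
                    min_records: int = 10) -> FlowNetwork:
    """Aggregate OD records into per-origin township flow counts D_ij.

    ``facility_table`` maps destination facility ids to the township (or
    street) hosting them; a DataFrame with a ``township_id`` column and
    facility ids as index is also accepted.  Origins whose total record
    count is below ``min_records`` are moved to ``excluded_origins``.
    """
    if isinstance(facility_table, pd.DataFrame):
        fac_map = facility_table["township_id"].to_dict()
    else:
        fac_map = dict(facility_table)
    if min_records < 1:
        raise ValueError("min_records must be a positive integer")

    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.dest_facility not in fac_map:
            raise KeyError(
                f"record {rec.respondent_id!r}: destination facility "
                f"{rec.dest_facility!r} cannot be resolved to a township"
            )
        key = (rec.origin_village, fac_map[rec.dest_facility])
        counts[key] = counts.get(key, 0) + 1

    if not counts:
        D = pd.DataFrame(dtype=int)
        return FlowNetwork(D=D, min_records=min_records)

    origins = sorted({o for o, _ in counts})
    dests = sorted({d for _, d in counts})
    D = pd.DataFrame(0, index=origins, columns=dests, dtype=int)
    for (o, d), c in counts.items():
        D.loc[o, d] = c

    totals = D.sum(axis=1)
    excluded = [
        (o, f"{int(totals[o])} records < min_records={min_records}")
        for o in origins if totals[o] < min_records
    ]
    keep = [o for o in origins if totals[o] >= min_records]
    return FlowNetwork(D=D.loc[keep], excluded_origins=excluded,
                       min_records=min_records)


def normalize_weights(network: FlowNetwork) -> FlowNetwork:
    """Attach W_ij = D_ij / sum_j D_ij; every retained row sums to 1."""
    if network.D.empty:
        network.W = network.D.astype(float)
        return network
    totals = network.D.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(
            f"retained origins with zero flow should have been excluded: {bad}"
        )
    network.W = network.D.div(totals, axis=0)
    return network


def build_graph(network: FlowNetwork,
                weight_mode: str = "proportion") -> nx.Graph:
    """Materialize the undirected weighted healthcare-seeking graph.

    Nodes are origin villages plus destination townships (a bipartite
    structure); the directed origin->destination weight is attached to a
    single undirected edge.  ``weight_mode`` selects the Eq.-style
    outflow proportion (default) or the raw count as edge weight;
    zero-weight edges are omitted.
    """
    if weight_mode not in ("proportion", "count"):
        raise ValueError("weight_mode must be 'proportion' or 'count'")
    M = network.W if weight_mode == "proportion" else network.D
    if M is None:
        raise ValueError("normalize_weights must run before build_graph "
                         "in proportion mode")
    overlap = set(M.index) & set(M.columns)
    if overlap:
        raise ValueError(
            f"origin and destination identifiers overlap: {sorted(overlap)}"
        )
    g = nx.Graph()
    for o in M.index:
        row = M.loc[o]
        for d in M.columns:
            w = float(row[d])
            if w > 0:
                g.add_edge(o, d, weight=w)
    return g


def write_ncol(graph_or_network, path) -> None:
    """Write the weighted edge list in NCOL format (source target weight).

    Weights are printed with 17 significant digits so a round trip is
    lossless.  Node identifiers must not contain whitespace.
    """
    g = graph_or_network
    if isinstance(g, FlowNetwork):
        g = build_graph(g)
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            if any(ch.isspace() for ch in str(u) + str(v)):
                raise ValueError(f"NCOL node names cannot contain whitespace: {u!r} {v!r}")
            fh.write(f"{u} {v} {data['weight']!r}\n")


def read_ncol(path) -> nx.Graph:
    """Read a whitespace-separated ``source target weight`` edge list."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'source target weight', "
                    f"got {line.strip()!r}"
                )
            u, v, w = parts
            try:
                weight = float(w)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad weight {w!r}") from exc
            g.add_edge(u, v, weight=weight)
    return g


def write_od_csv(records: list[ODRecord], path) -> None:
    pd.DataFrame(
        [(r.respondent_id, r.origin_village, r.dest_facility) for r in records],
        columns=["respondent_id", "origin_village_id", "dest_facility_id"],
    ).to_csv(path, index=False)


def read_od_csv(path) -> list[ODRecord]:
    df = pd.read_csv(path, dtype=str)
    required = {"respondent_id", "origin_village_id", "dest_facility_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ODRecord(r.respondent_id, r.origin_village_id, r.dest_facility_id)
        for r in df.itertuples(index=False)
    ]
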