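"""Seeded end-to-end pipeline: generate -> network -> detect -> identify
-> indicators -> select -> fit -> report.

Stages communicate only through declared file artifacts (CSV, NCOL,
GeoJSON, JSON) under one output directory, so any stage can be re-run or
replaced by user-supplied files with the same schema.  A run manifest
records the effective configuration, per-artifact SHA-256 checksums and
wall-clock times; deterministic stages reproduce byte-identical
artifacts under identical configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from edgevillages import choice as _choice
from edgevillages import community as _community
from edgevillages import enet as _enet
from edgevillages import flows as _flows
from edgevillages import hsa as _hsa
from edgevillages import indicators as _ind
from edgevillages import synthetic as _syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report",
           "STAGES"]

STAGES = ("generate", "network", "detect", "identify", "indicators",
          "select", "fit", "report")

# artifacts each stage needs from its predecessors
_REQUIRES = {
    "generate": [],
    "network": ["od_records.csv", "facilities.csv"],
    "detect": ["flow_graph.ncol"],
    "identify": ["od_records.csv", "facilities.csv", "villages.csv",
                 "partition.csv"],
    "indicators": ["villages.csv", "facilities.csv", "travel_times.csv",
                   "od_records.csv", "edge_villages.csv"],
    "select": ["indicators.csv", "edge_villages.csv"],
    "fit": ["indicators.csv", "edge_villages.csv"],
    "report": [],
}
_PRODUCES = {
    "generate": ["villages.csv", "facilities.csv", "od_records.csv",
                 "travel_times.csv", "patches.geojson", "truth.json"],
    "network": ["flow_graph.ncol", "excluded_origins.csv"],
    "detect": ["partition.csv", "partition.json"],
    "identify": ["hsa_summary.csv", "edge_villages.csv",
                 "hsa_overlay.geojson"],
    "indicators": ["indicators.csv"],
    "select": ["cv_table.csv", "selected_indicators.csv"],
    "fit": ["fit_summary.csv", "fit_metadata.json"],
    "report": ["summary.txt", "summary.json"],
}


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # generate
    county: _syn.CountyConfig | None = None
    # network
    min_records: int = 10
    weight_mode: str = "proportion"
    merge_map: dict[str, str] = field(default_factory=dict)
    # detect
    louvain_min_gain: float = 1e-9
    # identify
    share_threshold: float = 0.5
    aux_assignments: dict[str, int] = field(default_factory=dict)
    # select
    folds: int = 10
    alphas: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3,
                                 0.2, 0.1, 0.0)
    n_lambda: int = 50
    enet_family: str = "logistic"
    # fit
    base_alternative: str = "non-cross-region"
    n_draws: int = 500
    random_spec: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.county is None:
            self.county = _syn.CountyConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "county" in d and isinstance(d["county"], dict):
            d["county"] = _syn.CountyConfig(**d["county"])
        for key in ("stages", "alphas"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def checksums(self) -> dict[str, str]:
        out = {}
        for stage in self.stages.values():
            out.update(stage.get("artifacts", {}))
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages,
                       "warnings": self.warnings}, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate(config: PipelineConfig, outdir: Path) -> None:
    enabled = list(config.stages)
    for stage in enabled:
        for artifact in _REQUIRES[stage]:
            producer = next(s for s, arts in _PRODUCES.items()
                            if artifact in arts)
            if producer not in enabled and not (outdir / artifact).exists():
                raise ValueError(
                    f"stage '{stage}' needs {artifact!r} but stage "
                    f"'{producer}' is disabled and the file does not exist")


def _load_county(outdir: Path, config: PipelineConfig) -> _syn.County:
    """Rebuild a County view from the generate-stage artifacts."""
    vdf = pd.read_csv(outdir / "villages.csv").set_index("village_id")
    fdf = pd.read_csv(outdir / "facilities.csv").set_index("facility_id")
    travel = pd.read_csv(outdir / "travel_times.csv", index_col=0)
    villages = [
        _syn.Village(
            village_id=str(vid), township_id=str(r.township_id),
            centroid=(r.x_km, r.y_km), population=int(r.population),
            share_aged_60_plus=r.share_aged_60_plus,
            share_minority=r.share_minority,
            village_class=int(r.village_class),
            road_distance=r.road_distance, bus_frequency=r.bus_frequency,
            elevation=r.elevation, slope=r.slope)
        for vid, r in vdf.iterrows()
    ]
    facilities = [
        _syn.Facility(
            facility_id=str(fid), township_id=str(r.township_id),
            location=(r.x_km, r.y_km), wage_expenditure=r.wage_expenditure,
            n_physicians=int(r.n_physicians), n_nurses=int(r.n_nurses),
            n_health_technicians=int(r.n_health_technicians),
            scale=r.scale, in_county=bool(r.in_county),
            is_anchor=bool(r.is_anchor))
        for fid, r in fdf.iterrows()
    ]
    townships = sorted({v.township_id for v in villages})
    cohesion = vdf["cohesion"].to_dict()
    return _syn.County(config=config.county, villages=villages,
                       facilities=facilities, townships=townships,
                       travel_time_s=travel, patch_sets={},
                       cohesion=cohesion)


def _write_patches_geojson(county: _syn.County, path: Path) -> None:
    feats = []
    for vid, ps in sorted(county.patch_sets.items()):
        feats.append({
            "type": "Feature",
            "geometry": None,
            "properties": {
                "village_id": vid,
                "n_patches": len(ps.patches),
                "total_area_m2": ps.total_area,
                "patches": [{"perimeter_m": p, "area_m2": a}
                            for p, a in ps.patches],
            },
        })
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the enabled stages in order; any failure aborts with the stage
    named.  Returns the manifest with per-artifact checksums."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate(config, outdir)
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir", None)      # the hash describes the analysis, not its location
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest())

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, outdir, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        arts = {a: _sha256(outdir / a) for a in _PRODUCES[stage]
                if (outdir / a).exists()}
        manifest.stages[stage] = {
            "artifacts": arts,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    manifest.write(outdir / "manifest.json")
    return manifest


def _stage_generate(config, outdir, manifest):
    county = _syn.generate_county(config.county)
    records = _syn.simulate_od_records(county)
    county.villages_df().to_csv(outdir / "villages.csv")
    county.facilities_df().to_csv(outdir / "facilities.csv")
    county.travel_time_s.to_csv(outdir / "travel_times.csv")
    _flows.write_od_csv(records, outdir / "od_records.csv")
    _write_patches_geojson(county, outdir / "patches.geojson")
    (outdir / "truth.json").write_text(
        json.dumps(county.truth, indent=2, sort_keys=True))


def _build_network(config, outdir):
    records = _flows.read_od_csv(outdir / "od_records.csv")
    records = _flows.apply_merge_map(records, config.merge_map)
    fdf = pd.read_csv(outdir / "facilities.csv", dtype={"facility_id": str})
    fac_map = dict(zip(fdf["facility_id"], fdf["township_id"].astype(str)))
    network = _flows.aggregate_flows(records, fac_map,
                                     min_records=config.min_records)
    return _flows.normalize_weights(network)


def _stage_network(config, outdir, manifest):
    network = _build_network(config, outdir)
    graph = _flows.build_graph(network, weight_mode=config.weight_mode)
    _flows.write_ncol(graph, outdir / "flow_graph.ncol")
    pd.DataFrame(network.excluded_origins,
                 columns=["origin", "reason"]).to_csv(
        outdir / "excluded_origins.csv", index=False)
    for origin, reason in network.excluded_origins:
        manifest.warnings.append(f"origin {origin} excluded: {reason}")


def _stage_detect(config, outdir, manifest):
    graph = _flows.read_ncol(outdir / "flow_graph.ncol")
    result = _community.louvain(graph, seed=config.seed,
                                min_gain=config.louvain_min_gain)
    rows = []
    for part in result.levels:
        for node, comm in sorted(part.assignment.items()):
            rows.append({"node_id": node, "community_id": comm,
                         "level": part.level})
    pd.DataFrame(rows).to_csv(outdir / "partition.csv", index=False)
    qs = [p.modularity for p in result.levels]
    (outdir / "partition.json").write_text(json.dumps({
        "levels": [{"level": p.level, "modularity": p.modularity,
                    "n_communities": p.n_communities}
                   for p in result.levels],
        "final_modularity": result.final.modularity,
        "final_n_communities": result.final.n_communities,
    }, indent=2, sort_keys=True))
    for q in qs:
        if not 0.3 <= q <= 0.7:
            msg = (f"modularity {q:.4f} outside the 0.3-0.7 plausibility "
                   "band typical of real-world networks")
            logger.warning(msg)
            manifest.warnings.append(msg)


def _stage_identify(config, outdir, manifest):
    county = _load_county(outdir, config)
    network = _build_network(config, outdir)
    pdf = pd.read_csv(outdir / "partition.csv")
    last = pdf[pdf["level"] == pdf["level"].max()]
    partition = _community.Partition(
        assignment=dict(zip(last["node_id"].astype(str),
                            last["community_id"].astype(int))),
        modularity=float("nan"), level=int(pdf["level"].max()))
    delineation = _hsa.delineate_hsas(partition, county)
    aux = dict(config.aux_assignments)
    truth_path = outdir / "truth.json"
    if truth_path.exists():
        # synthetic runs: the generator's known care-seeking pattern plays
        # the role of the expert interviews for zero-flow villages
        functional = json.loads(truth_path.read_text()).get(
            "functional_township", {})
        for unit in delineation.unassigned:
            target = delineation.township_hsa.get(functional.get(unit))
            if unit not in aux and target is not None:
                aux[unit] = target
    delineation = _hsa.postprocess_unassigned(
        delineation, aux_assignments=aux,
        network=_flows.aggregate_flows(
            _flows.read_od_csv(outdir / "od_records.csv"),
            pd.read_csv(outdir / "facilities.csv",
                        dtype={"facility_id": str}).set_index("facility_id"),
            min_records=1),
        county=county)
    edge_table = _hsa.identify_edge_villages(
        delineation, network, county, share_threshold=config.share_threshold)
    delineation.summary().to_csv(outdir / "hsa_summary.csv")
    edge_table.to_csv(outdir / "edge_villages.csv")
    feats = []
    vdf = pd.read_csv(outdir / "villages.csv").set_index("village_id")
    for vid, row in edge_table.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [vdf.loc[vid, "x_km"],
                                         vdf.loc[vid, "y_km"]]},
            "properties": {"village_id": vid, "hsa_id": int(row["hsa_id"]),
                           "is_edge": bool(row["is_edge"])},
        })
    (outdir / "hsa_overlay.geojson").write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, sort_keys=True))


def _stage_indicators(config, outdir, manifest):
    county = _load_county(outdir, config)
    network = _build_network(config, outdir)
    edge_table = pd.read_csv(outdir / "edge_villages.csv").set_index("village_id")
    table = _ind.assemble_indicators(county, network=network,
                                     edge_table=edge_table)
    table.to_csv(outdir / "indicators.csv")


def _selection_design(outdir):
    table = pd.read_csv(outdir / "indicators.csv").set_index("village_id")
    cols = list(_ind.ACTIVE_INDICATORS + _ind.PASSIVE_INDICATORS)
    X = table[cols]
    keep = [c for c in cols if X[c].std(ddof=0) > 0]
    dropped = sorted(set(cols) - set(keep))
    y = table["is_edge"].astype(float)
    return table, X[keep], y, keep, dropped


def _stage_select(config, outdir, manifest):
    _, X, y, keep, dropped = _selection_design(outdir)
    for c in dropped:
        msg = f"indicator {c!r} has zero variance; dropped from selection"
        logger.warning(msg)
        manifest.warnings.append(msg)
    if y.nunique() < 2 and config.enet_family == "logistic":
        msg = ("edge-village outcome is single-class; skipping feature "
               "selection")
        logger.warning(msg)
        manifest.warnings.append(msg)
        pd.DataFrame().to_csv(outdir / "cv_table.csv", index=False)
        pd.DataFrame().to_csv(outdir / "selected_indicators.csv", index=False)
        return
    cv = _enet.cross_validate(X.to_numpy(), y.to_numpy(),
                              family=config.enet_family, folds=config.folds,
                              alphas=config.alphas, n_lambda=config.n_lambda,
                              seed=config.seed, names=keep)
    groups = {c: ("active" if c in _ind.ACTIVE_INDICATORS else "passive")
              for c in keep}
    selected = _enet.select_features(cv, X.to_numpy(), y.to_numpy(),
                                     names=keep, groups=groups)
    cv.to_csv(outdir / "cv_table.csv", index=False)
    selected.to_csv(outdir / "selected_indicators.csv", index=False)


def _stage_fit(config, outdir, manifest):
    table = pd.read_csv(outdir / "indicators.csv").set_index("village_id")
    edge_table = pd.read_csv(outdir / "edge_villages.csv").set_index("village_id")
    observed = edge_table["cross_township_share"].notna()
    dataset = _choice.build_choice_dataset(
        table.loc[observed[table.index]].copy(),
        edge_table, base_alternative=config.base_alternative)
    fit = _choice.fit_logit(dataset, random_spec=config.random_spec or None,
                            n_draws=config.n_draws, seed=config.seed)
    summary = fit.summary()
    summary.to_csv(outdir / "fit_summary.csv")
    chi2, df, p = _choice.wald_test(fit)
    M, _, names = dataset.design()
    vifs = _choice.vif(pd.DataFrame(M[:, [j for j, n in enumerate(names)
                                          if n != "ASC"]],
                                    columns=[n for n in names if n != "ASC"]))
    (outdir / "fit_metadata.json").write_text(json.dumps({
        "loglik": fit.loglik, "wald_chi2": chi2, "wald_df": df, "wald_p": p,
        "n_cases": len(dataset.case_ids), "n_draws": fit.n_draws,
        "base_alternative": config.base_alternative,
        "vif": vifs.round(6).to_dict(),
    }, indent=2, sort_keys=True))


def _stage_report(config, outdir, manifest):
    report(outdir)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "network": _stage_network,
    "detect": _stage_detect,
    "identify": _stage_identify,
    "indicators": _stage_indicators,
    "select": _stage_select,
    "fit": _stage_fit,
    "report": _stage_report,
}


def report(outdir) -> dict:
    """Render plain-text and JSON summaries of whatever outputs exist."""
    outdir = Path(outdir)
    summary: dict = {"missing": []}
    lines: list[str] = ["Edge-village analysis summary",
                        "=" * 31]

    pj = outdir / "partition.json"
    if pj.exists():
        part = json.loads(pj.read_text())
        summary["hsa_detection"] = part
        lines.append("Louvain levels:")
        for lv in part["levels"]:
            lines.append(f"  level {lv['level']}: {lv['n_communities']} "
                         f"communities, modularity {lv['modularity']:.7f}")
    else:
        summary["missing"].append("partition.json")

    hs = outdir / "hsa_summary.csv"
    if hs.exists():
        hsa = pd.read_csv(hs)
        summary["n_hsas"] = int(len(hsa))
        lines.append(f"HSAs delineated: {len(hsa)}")
    else:
        summary["missing"].append("hsa_summary.csv")

    ev = outdir / "edge_villages.csv"
    if ev.exists():
        et = pd.read_csv(ev)
        edges = et[et["is_edge"]]
        summary["n_edge_villages"] = int(len(edges))
        summary["edge_villages"] = [
            {"village": r.village_id, "township": r.township_id,
             "main_outflow_destination": r.main_outflow_destination}
            for r in edges.itertuples()]
        if len(edges):
            lines.append(f"Edge villages ({len(edges)}):")
            for e in summary["edge_villages"]:
                lines.append(f"  {e['village']} ({e['township']}) -> "
                             f"{e['main_outflow_destination']}")
        else:
            lines.append("Edge villages: none")
    else:
        summary["missing"].append("edge_villages.csv")

    si = outdir / "selected_indicators.csv"
    if si.exists():
        sel = pd.read_csv(si)
        summary["selected_indicators"] = (
            sel["indicator"].tolist() if "indicator" in sel else [])
        lines.append("Selected indicators: "
                     + (", ".join(summary["selected_indicators"]) or "none"))
    else:
        summary["missing"].append("selected_indicators.csv")

    fm = outdir / "fit_metadata.json"
    if fm.exists():
        meta = json.loads(fm.read_text())
        summary["choice_model"] = meta
        lines.append(f"Choice model: log-likelihood {meta['loglik']:.3f}, "
                     f"Wald chi2({meta['wald_df']}) = {meta['wald_chi2']:.2f} "
                     f"(p = {meta['wald_p']:.4f})")
    else:
        summary["missing"].append("fit_metadata.json")

    fs = outdir / "fit_summary.csv"
    if fs.exists():
        lines.append("Coefficients:")
        for r in pd.read_csv(fs, index_col=0).itertuples():
            lines.append(f"  {r.Index:<16s} {r.coefficient:+10.5f} "
                         f"(se {r.std_error:.5f}, p {r.p_value:.3f})")

    text = "\n".join(lines) + "\n"
    (outdir / "summary.txt").write_text(text)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    return summary
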