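"""End-to-end orchestration: simulate → resistance → nodes → circuit → lcp →
validate, with a run manifest for reproducibility.

Each stage reads the previous stage's on-disk outputs, so any stage can be
re-run independently; a manifest (resolved config, seed, per-stage timing,
output checksums) is written with every run. All of the study's printed
settings — 150 m cells, 1-6 layer and 1-10 cumulative resistance scales,
150 m node-merge radius, top-5% ranking, 1200 m corridors, 10 km clip
buffer — are config defaults, not hard-coded constants.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit, corridors, resistance, synthetic, validation
from .grid import Grid, read_ascii_grid, write_ascii_grid
from .io import (read_geojson, read_matrix_csv, read_nodes_csv, write_geojson,
                 write_matrix_csv, write_nodes_csv)
from .nodes import FocalNodeSet, merge_nodes, reach_midpoint, snap_to_grid

logger = logging.getLogger("waveways")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "resistance", "nodes", "circuit", "lcp", "validate")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    landscape: synthetic.LandscapeConfig = field(
        default_factory=synthetic.LandscapeConfig)
    n_snag_sites: int = 20
    # detection intensity scaled to the default toy extent (the study-scale
    # DetectionModel defaults would saturate every site pair on ~81 km^2):
    # sparse outcomes mirror the heavily unbalanced transit data the Firth
    # fit is designed for
    detection: synthetic.DetectionModel = field(
        default_factory=lambda: synthetic.DetectionModel(
            n_individuals={"grizzly": 6, "black": 18},
            home_range_sigma_m=1500.0, baseline_detection_prob=0.08))
    merge_radius_m: float = 150.0
    clip_buffer_m: float = 10000.0
    top_fraction: float = 0.05
    corridor_width_m: float = 1200.0
    keep_pair_maps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "landscape" in kwargs:
            ls = dict(kwargs["landscape"])
            for key in ("extent_m", "species_labels"):
                if key in ls:
                    ls[key] = tuple(ls[key])
            kwargs["landscape"] = synthetic.LandscapeConfig(**ls)
        if "detection" in kwargs:
            kwargs["detection"] = synthetic.DetectionModel(**kwargs["detection"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    ls = cfg.landscape
    elev = synthetic.generate_elevation(ls)
    land = synthetic.generate_land_mask(elev, ls)
    cover, age = synthetic.generate_landcover(elev, ls)
    net = synthetic.generate_hydrology(elev, ls)
    sites = synthetic.generate_snag_sites(ls, cfg.n_snag_sites, land=land)
    detections = synthetic.simulate_detections(sites, cfg.detection,
                                               seed=ls.seed, land=land)
    write_ascii_grid(elev, out / "elevation.asc")
    write_ascii_grid(land.like(land.data.astype(float)), out / "land.asc")
    write_ascii_grid(cover.like(cover.data.astype(float)),
                     out / "landcover.asc")
    write_ascii_grid(age, out / "stand_age.asc")
    write_geojson(net.streams, out / "streams.geojson")
    write_geojson(net.reaches, out / "reaches.geojson")
    write_nodes_csv(sites, out / "snag_sites.csv")
    detections.to_csv(out / "detections.csv", index=False)
    logger.info("simulate: %d land cells, %d streams, %d reaches, "
                "%d sites, %d detections", int(land.data.sum()),
                len(net.streams), len(net.reaches), len(sites),
                len(detections))
    return {"land_cells": int(land.data.sum()), "n_streams": len(net.streams),
            "n_reaches": len(net.reaches), "n_sites": len(sites),
            "n_detections": len(detections)}


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing {name}; run the '{stage}' stage first")
    return p


def _stage_resistance(cfg: RunConfig, out: Path) -> dict:
    elev = read_ascii_grid(_require(out, "elevation.asc", "simulate"))
    land = read_ascii_grid(_require(out, "land.asc", "simulate"))
    cover = read_ascii_grid(_require(out, "landcover.asc", "simulate"))
    age = read_ascii_grid(_require(out, "stand_age.asc", "simulate"))
    land_bool = land.like(land.data > 0.5)
    water_bool = land.like(~(land.data > 0.5))

    tri = resistance.terrain_ruggedness_index(elev)
    tri_layer = resistance.classify_continuous(tri, resistance.TRI_SCHEME)
    cover_int = cover.like(np.asarray(cover.data, dtype=int))
    lc_layer = resistance.classify_landcover(cover_int, age)
    dist = resistance.distance_to_shore(water_bool)
    water_layer = resistance.classify_water(dist, water_bool)
    cum = resistance.combine_layers(tri_layer, lc_layer, water_layer)

    write_ascii_grid(tri, out / "tri.asc")
    write_ascii_grid(cum.grid, out / "cumulative_resistance.asc")
    vals = cum.grid.valid_values()
    logger.info("resistance: %d cells, cumulative range [%.2f, %.2f]",
                cum.grid.n_valid, vals.min(), vals.max())
    return {"n_cells": cum.grid.n_valid,
            "min": float(vals.min()), "max": float(vals.max())}


def _stage_nodes(cfg: RunConfig, out: Path) -> dict:
    cum = read_ascii_grid(_require(out, "cumulative_resistance.asc",
                                   "resistance"))
    reaches = read_geojson(_require(out, "reaches.geojson", "simulate"))
    pts, meta = [], []
    for (wcode, species), sub in reaches.groupby(["watershed_code",
                                                  "species"]):
        mid = reach_midpoint(list(sub["geometry"]))
        pts.append([mid.x, mid.y])
        meta.append((wcode, species))
    raw = FocalNodeSet.from_points(
        np.array(pts), source="reach_midpoint",
        watershed_code=[m[0] for m in meta], species=[m[1] for m in meta])
    merged = merge_nodes(raw, cfg.merge_radius_m)
    snapped = snap_to_grid(merged, cum)
    write_nodes_csv(snapped, out / "focal_nodes.csv")
    logger.info("nodes: %d midpoints -> %d merged -> %d snapped (%d pairs)",
                len(raw), len(merged), len(snapped), snapped.n_pairs)
    return {"n_midpoints": len(raw), "n_nodes": len(snapped),
            "n_pairs": snapped.n_pairs}


def _stage_circuit(cfg: RunConfig, out: Path) -> dict:
    cum = read_ascii_grid(_require(out, "cumulative_resistance.asc",
                                   "resistance"))
    nodes = read_nodes_csv(_require(out, "focal_nodes.csv", "nodes"))
    graph = circuit.build_graph(cum)
    result = circuit.pairwise_all(graph, nodes,
                                  keep_pair_maps=cfg.keep_pair_maps)
    write_ascii_grid(result.cumulative_current, out / "cumulative_current.asc")
    write_matrix_csv(result.R, result.node_ids, out / "effective_resistance.csv")
    write_matrix_csv(result.G, result.node_ids, out / "effective_conductance.csv")

    # snag-site conductance for the validation stage, on the same surface
    sites = read_nodes_csv(_require(out, "snag_sites.csv", "simulate"))
    sites_snapped = snap_to_grid(sites, cum)
    site_result = circuit.pairwise_all(graph, sites_snapped)
    write_matrix_csv(site_result.G, site_result.node_ids,
                     out / "site_conductance.csv")
    write_nodes_csv(sites_snapped, out / "snag_sites_snapped.csv")
    logger.info("circuit: %d graph nodes, %d focal pairs, %d site pairs",
                graph.n_nodes, result.n_pairs, site_result.n_pairs)
    return {"n_graph_nodes": graph.n_nodes, "n_pairs": result.n_pairs,
            "n_site_pairs": site_result.n_pairs}


def _stage_lcp(cfg: RunConfig, out: Path) -> dict:
    cur = read_ascii_grid(_require(out, "cumulative_current.asc", "circuit"))
    nodes = read_nodes_csv(_require(out, "focal_nodes.csv", "nodes"))
    cost = corridors.current_to_cost(cur)
    paths = corridors.fete_lcps(cost, nodes)
    top = corridors.rank_paths(paths, cfg.top_fraction)
    corridor_polys = corridors.buffer_corridors(top, cfg.corridor_width_m)
    paths.table.to_csv(out / "lcp_all.csv", index=False)
    top.table.to_csv(out / "lcp_top.csv", index=False)
    geo = pd.DataFrame({
        "site_a": [k[0] for k in top.geometries],
        "site_b": [k[1] for k in top.geometries],
        "geometry": list(top.geometries.values())})
    write_geojson(geo, out / "lcp_top.geojson")
    write_geojson(pd.DataFrame({"name": ["corridors"],
                                "geometry": [corridor_polys]}),
                  out / "corridors.geojson")
    logger.info("lcp: %d paths, top %d kept, corridor area %.1f km^2",
                len(paths), len(top), corridor_polys.area / 1e6)
    return {"n_paths": len(paths), "n_top": len(top),
            "n_skipped": len(paths.skipped),
            "corridor_area_km2": corridor_polys.area / 1e6}


def _stage_validate(cfg: RunConfig, out: Path) -> dict:
    detections = pd.read_csv(_require(out, "detections.csv", "simulate"))
    sites = read_nodes_csv(_require(out, "snag_sites_snapped.csv", "circuit"))
    gmat = read_matrix_csv(_require(out, "site_conductance.csv", "circuit"))
    transits = validation.build_transit_edges(detections, sites)
    ids = list(sites.table["node_id"])
    pos = {sid: k for k, sid in enumerate(ids)}
    gvals = gmat.to_numpy()
    transits["G"] = [gvals[pos[a], pos[b]]
                     for a, b in zip(transits["site_a"], transits["site_b"])]
    transits.to_csv(out / "transits.csv", index=False)
    fit, report = validation.validate_surface(transits)
    report["coefficients"] = dict(zip(fit.names, fit.beta.tolist()))
    with open(out / "validation.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "validation.txt", "w") as fh:
        fh.write(fit.summary().to_string())
        fh.write(f"\n\nconverged in {fit.n_iter} iterations; "
                 f"{report['n_transited']} of {report['n_pairs']} "
                 f"pairs transited\n")
    logger.info("validate: OR conductance %.3f, distance %.3f "
                "(%d/%d transited)", report["odds_ratio"]["conductance"],
                report["odds_ratio"]["distance"], report["n_transited"],
                report["n_pairs"])
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "resistance": _stage_resistance,
    "nodes": _stage_nodes,
    "circuit": _stage_circuit,
    "lcp": _stage_lcp,
    "validate": _stage_validate,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; write a manifest; return it."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(cfg), "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        info = _STAGE_FUNCS[stage](cfg, out)
        manifest["stages"][stage] = {
            "info": info, "seconds": round(time.perf_counter() - t0, 3)}
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    try:
        from importlib.metadata import version
        d["waveways_version"] = version("waveways")
    except Exception:
        d["waveways_version"] = "unknown"
    return d
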