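"""Least-cost corridors from the cumulative current map.

The continuous current map predicts *all* possible movement, which is hard
for planners to act on. This module simplifies it into discrete routes: the
current map is inverted into a conductance-based cost surface (high current =
cheap to traverse), one least-cost path is traced between every focal-node
pair (from-everywhere-to-everywhere), paths are ranked by accumulated cost,
the cheapest 5% are kept, and those are buffered into fixed-width candidate
corridors whose overlap with protected areas is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.ops import unary_union

from .grid import Grid
from .nodes import FocalNodeSet

__all__ = ["CostGraph", "PathSet", "current_to_cost", "fete_lcps",
           "rank_paths", "top_fraction_count", "buffer_corridors",
           "overlap_with_polygons"]


@dataclass
class CostGraph:
    """Raster graph whose edge costs are distance over mean conductance."""

    cell_index: np.ndarray        # (n, 2) row, col
    edges: np.ndarray             # (m, 2) node indices
    costs: np.ndarray             # (m,)
    grid: Grid

    def __post_init__(self) -> None:
        if not np.isfinite(self.costs).all() or (self.costs <= 0).any():
            raise ValueError("edge costs must be positive and finite")

    @property
    def n_nodes(self) -> int:
        return len(self.cell_index)

    def matrix(self):
        i, j = self.edges[:, 0], self.edges[:, 1]
        n = self.n_nodes
        return coo_matrix(
            (np.concatenate([self.costs, self.costs]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n)).tocsr()


@dataclass
class PathSet:
    """Least-cost paths per focal pair, with ranking metadata.

    ``table`` columns: site_a, site_b, accumulated_cost, length_m, rank
    (after ranking); ``geometries`` maps (site_a, site_b) to a LineString of
    traversed cell centres; ``skipped`` lists disconnected pairs.
    """

    table: pd.DataFrame
    geometries: dict
    skipped: list

    def __len__(self) -> int:
        return len(self.table)


def current_to_cost(current: Grid, epsilon: float | None = None) -> CostGraph:
    """Conductance cost surface from a current-density grid.

    Cell conductance is current plus a small floor ``epsilon`` (default
    1e-6 × max current) so zero-current cells stay traversable at high cost;
    the edge cost between neighbours is inter-cell distance divided by the
    mean of their conductances (distance ×√2 on diagonals).
    """
    cur = np.asarray(current.data, dtype=float)
    valid = ~current.nodata_mask & np.isfinite(cur)
    if (cur[valid] < 0).any():
        raise ValueError("current must be non-negative")
    cmax = cur[valid].max() if valid.any() else 0.0
    if cmax == 0:
        raise ValueError("all-zero current map")
    if epsilon is None:
        epsilon = 1e-6 * cmax
    cond = cur + epsilon

    nr, nc = current.shape
    node_id = np.full((nr, nc), -1, dtype=int)
    cells = np.argwhere(valid)
    node_id[valid] = np.arange(len(cells))
    ei, ej, ec = [], [], []
    d0 = current.cell_size
    for dr, dc in [(0, 1), (1, -1), (1, 0), (1, 1)]:
        rs = slice(max(dr, 0), nr + min(dr, 0))
        cs = slice(max(dc, 0), nc + min(dc, 0))
        rd = slice(max(-dr, 0), nr + min(-dr, 0))
        cd = slice(max(-dc, 0), nc + min(-dc, 0))
        ok = valid[rd, cd] & valid[rs, cs]
        a, b = node_id[rd, cd][ok], node_id[rs, cs][ok]
        mean_c = 0.5 * (cond[rd, cd][ok] + cond[rs, cs][ok])
        dist = d0 * (np.sqrt(2.0) if dr != 0 and dc != 0 else 1.0)
        ei.append(a)
        ej.append(b)
        ec.append(dist / mean_c)
    edges = np.column_stack([np.concatenate(ei), np.concatenate(ej)])
    return CostGraph(cells, edges, np.concatenate(ec), current)


def fete_lcps(cost: CostGraph, nodes: FocalNodeSet) -> PathSet:
    """From-everywhere-to-everywhere least-cost paths between focal nodes.

    One undirected path per unordered pair (costs are symmetric), found by
    a Dijkstra search from each node with predecessor tracking; scipy's
    implementation breaks ties deterministically. Disconnected pairs are
    omitted and flagged.
    """
    tbl = nodes.table
    if len(tbl) < 2:
        raise ValueError("need at least 2 focal nodes")
    if "row" not in tbl.columns:
        raise ValueError("nodes are not snapped to the grid")
    node_map = np.full(cost.grid.shape, -1, dtype=int)
    node_map[tuple(cost.cell_index.T)] = np.arange(cost.n_nodes)
    gidx = []
    for _, rec in tbl.iterrows():
        g = node_map[int(rec["row"]), int(rec["col"])]
        if g < 0:
            raise ValueError(f"node {rec['node_id']} is not on a valid cell")
        gidx.append(int(g))
    gidx = np.array(gidx)
    mat = cost.matrix()

    rows_out, geoms, skipped = [], {}, []
    ids = tbl["node_id"].to_numpy()
    for a in range(len(gidx)):
        dist, pred = dijkstra(mat, directed=False, indices=gidx[a],
                              return_predecessors=True)
        for b in range(a + 1, len(gidx)):
            key = (ids[a], ids[b])
            if not np.isfinite(dist[gidx[b]]):
                skipped.append(key)
                continue
            chain = [gidx[b]]
            while chain[-1] != gidx[a]:
                p = pred[chain[-1]]
                if p < 0:
                    break
                chain.append(p)
            chain = chain[::-1]
            rc = cost.cell_index[chain]
            xs, ys = cost.grid.cell_center(rc[:, 0], rc[:, 1])
            geom = LineString(np.column_stack([xs, ys])) if len(chain) > 1 \
                else None
            geoms[key] = geom
            rows_out.append({"site_a": ids[a], "site_b": ids[b],
                             "accumulated_cost": float(dist[gidx[b]]),
                             "length_m": geom.length if geom else 0.0})
    return PathSet(pd.DataFrame(rows_out), geoms, skipped)


def top_fraction_count(n: int, fraction: float) -> int:
    """Number of paths kept by a top-``fraction`` ranking: ``ceil(f n)``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return int(ceil(fraction * n))


def rank_paths(paths: PathSet, fraction: float = 0.05) -> PathSet:
    """Keep the ``ceil(fraction × n)`` paths of lowest accumulated cost.

    Ties beyond the cutoff are broken by (site_a, site_b) pair id so the
    selection is deterministic.
    """
    if len(paths) == 0:
        raise ValueError("empty path set")
    k = top_fraction_count(len(paths), fraction)
    tbl = paths.table.sort_values(
        ["accumulated_cost", "site_a", "site_b"]).head(k).copy()
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    keys = set(zip(tbl["site_a"], tbl["site_b"]))
    geoms = {k_: g for k_, g in paths.geometries.items() if k_ in keys}
    return PathSet(tbl.reset_index(drop=True), geoms, list(paths.skipped))


def buffer_corridors(paths: PathSet, width_m: float = 1200.0):
    """Buffer each path into a corridor of total width ``width_m``.

    The buffer radius is half the corridor width; overlapping corridors are
    dissolved into one multipolygon. An empty path set (or zero width) gives
    an empty geometry.
    """
    if width_m <= 0 or not paths.geometries:
        return MultiPolygon([])
    polys = [g.buffer(width_m / 2.0) for g in paths.geometries.values()
             if g is not None]
    merged = unary_union(polys)
    if isinstance(merged, Polygon):
        merged = MultiPolygon([merged])
    return merged


def overlap_with_polygons(paths: PathSet, protected) -> tuple[float, pd.DataFrame]:
    """Path length inside/outside a protected-area multipolygon.

    Returns the overall fraction of accumulated path length outside the
    protected areas and a per-path table (length_m, inside_m, outside_m,
    outside_fraction).
    """
    if protected is not None and not protected.is_valid:
        protected = protected.buffer(0)
        if not protected.is_valid:
            raise ValueError("protected-area geometry could not be repaired")
    rows = []
    for key, geom in paths.geometries.items():
        if geom is None:
            continue
        total = geom.length
        inside = geom.intersection(protected).length if protected is not None \
            and not protected.is_empty else 0.0
        rows.append({"site_a": key[0], "site_b": key[1], "length_m": total,
                     "inside_m": inside, "outside_m": total - inside,
                     "outside_fraction": (total - inside) / total
                     if total > 0 else 0.0})
    tbl = pd.DataFrame(rows)
    tot = tbl["length_m"].sum()
    frac_outside = float(tbl["outside_m"].sum() / tot) if tot > 0 else 0.0
    return frac_outside, tbl
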