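"""Focal nodes: salmon-reach midpoints and snag sites on the resistance grid.

Connectivity is computed between *focal nodes*. For the salmon analysis each
node is the midpoint of all spawning reaches of one species on one stream;
midpoints closer together than the cell resolution are merged to their mean
centre, and every node is snapped to a valid cell of the resistance grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiLineString, Point
from shapely.ops import linemerge

from .grid import Grid

__all__ = ["FocalNodeSet", "reach_midpoint", "merge_nodes", "snap_to_grid"]


@dataclass
class FocalNodeSet:
    """Labelled points, optionally snapped to grid cells.

    ``table`` columns: node_id, x, y, source and, when available,
    watershed_code, species, row, col, merged_ids.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.table) and self.table["node_id"].duplicated().any():
            raise ValueError("node ids must be unique")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def n_pairs(self) -> int:
        n = len(self)
        return n * (n - 1) // 2

    def pair_index(self) -> pd.DataFrame:
        """All unordered node pairs (id_a < id_b by position) with distances."""
        ids = self.table["node_id"].to_numpy()
        xy = self.xy
        ia, ib = np.triu_indices(len(ids), k=1)
        d = np.hypot(*(xy[ia] - xy[ib]).T)
        return pd.DataFrame({"site_a": ids[ia], "site_b": ids[ib],
                             "distance_m": d})

    @classmethod
    def from_points(cls, xy: np.ndarray, source: str,
                    ids=None, **extra) -> "FocalNodeSet":
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        if ids is None:
            ids = np.arange(len(xy))
        tbl = pd.DataFrame({"node_id": ids, "x": xy[:, 0], "y": xy[:, 1],
                            "source": source})
        for k, v in extra.items():
            tbl[k] = v
        return cls(tbl)


def reach_midpoint(reaches) -> Point:
    """Point at half the total arc length of one species' reaches on a stream.

    Multi-part reaches are concatenated in the order given (downstream to
    upstream); the midpoint always lies on one of the parts.
    """
    if isinstance(reaches, (LineString, MultiLineString)):
        parts = list(reaches.geoms) if isinstance(reaches, MultiLineString) \
            else [reaches]
    else:
        parts = []
        for g in reaches:
            merged = linemerge(g) if isinstance(g, MultiLineString) else g
            if isinstance(merged, MultiLineString):
                parts.extend(merged.geoms)
            else:
                parts.append(merged)
    total = sum(p.length for p in parts)
    if total == 0:
        raise ValueError("zero-length reach geometry")
    half = total / 2.0
    for p in parts:
        if half <= p.length:
            return p.interpolate(half)
        half -= p.length
    return parts[-1].interpolate(parts[-1].length)  # numeric edge


def merge_nodes(nodes: FocalNodeSet, radius_m: float = 150.0) -> FocalNodeSet:
    """Merge nodes within ``radius_m`` of one another to their mean centre.

    Clusters are single-linkage connected components of the within-radius
    relation, so the result is independent of input order; each component is
    replaced by one node at the unweighted mean of its members.
    """
    if radius_m < 0:
        raise ValueError("radius must be non-negative")
    n = len(nodes)
    if n == 0:
        return FocalNodeSet(nodes.table.copy())
    xy = nodes.xy
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(radius_m):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    rows = []
    src = nodes.table
    for root in np.unique(roots):
        members = np.flatnonzero(roots == root)
        sub = src.iloc[members]
        rec = {"node_id": sub["node_id"].iloc[0],
               "x": xy[members, 0].mean(), "y": xy[members, 1].mean(),
               "source": sub["source"].iloc[0],
               "merged_ids": ",".join(str(i) for i in sub["node_id"])}
        for col in ("watershed_code", "species"):
            if col in sub.columns:
                rec[col] = ";".join(sorted(set(map(str, sub[col]))))
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("node_id").reset_index(drop=True)
    return FocalNodeSet(out)


def snap_to_grid(nodes: FocalNodeSet, grid: Grid,
                 max_search_cells: int = 2) -> FocalNodeSet:
    """Assign each node its containing grid cell.

    A node landing on a nodata cell is moved to the nearest valid cell within
    ``max_search_cells`` (Chebyshev); two nodes resolving to the same cell are
    merged into one (member ids recorded), so no two nodes share a cell.
    """
    tbl = nodes.table.copy()
    rows, cols = [], []
    for x, y in nodes.xy:
        r, c = grid.xy_to_rowcol(x, y)
        r, c = int(r), int(c)
        if not grid.contains_rowcol(r, c) or grid.nodata_mask[r, c]:
            best = None
            for dr in range(-max_search_cells, max_search_cells + 1):
                for dc in range(-max_search_cells, max_search_cells + 1):
                    rr, cc = r + dr, c + dc
                    if grid.contains_rowcol(rr, cc) and \
                            not grid.nodata_mask[rr, cc]:
                        cx, cy = grid.cell_center(rr, cc)
                        d = (cx - x) ** 2 + (cy - y) ** 2
                        if best is None or d < best[0]:
                            best = (d, rr, cc)
            if best is None:
                raise ValueError(
                    f"point ({x:.0f}, {y:.0f}) farther than "
                    f"{max_search_cells} cells from any valid cell")
            r, c = best[1], best[2]
        rows.append(r)
        cols.append(c)
    tbl["row"], tbl["col"] = rows, cols
    # collapse cell collisions onto one node
    out_rows = []
    for (r, c), sub in tbl.groupby(["row", "col"], sort=True):
        rec = sub.iloc[0].to_dict()
        if len(sub) > 1:
            rec["merged_ids"] = ",".join(str(i) for i in sub["node_id"])
        cx, cy = grid.cell_center(r, c)
        rec["x"], rec["y"] = float(cx), float(cy)
        out_rows.append(rec)
    out = pd.DataFrame(out_rows).sort_values("node_id").reset_index(drop=True)
    return FocalNodeSet(out)
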