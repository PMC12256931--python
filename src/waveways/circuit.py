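"""Circuit-theory connectivity: raster → resistor network → current maps.

The resistance raster becomes a resistor network: every valid cell is a node,
connected to its eight neighbours; the edge between cells *i* and *j* carries
resistance ``(r_i + r_j) / 2``, scaled by √2 for diagonal neighbours. For a
focal pair, one ampere is injected at the source and withdrawn at the target;
the node potentials solve the conductance-Laplacian system ``L v = b``.
Effective resistance is the potential drop between the pair; current density
at a cell (half the summed magnitude of its incident branch currents) is
proportional to random-walk passage probability. Summing the per-pair current
maps over all focal pairs gives the cumulative current map; pinch points are
cells of concentrated current.

Disconnection is data, not failure: islands are real in this seascape, so a
pair in different components gets infinite effective resistance and zero
conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import factorized

from .grid import Grid
from .nodes import FocalNodeSet
from .resistance import CumulativeResistance

__all__ = ["ResistanceGraph", "CircuitResult", "build_graph", "solve_pair",
           "pairwise_all", "effective_conductance"]

@dataclass
class ResistanceGraph:
    """Sparse resistor network over the valid cells of a raster."""

    cell_index: np.ndarray          # (n, 2) row, col of each node
    edges: np.ndarray               # (m, 2) int node indices, i < j
    resistances: np.ndarray         # (m,) edge resistances, > 0
    grid: Grid | None = None        # georeferencing of the source raster
    component: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.resistances <= 0).any():
            raise ValueError("edge resistances must be positive")
        if self.component is None:
            n = len(self.cell_index)
            adj = coo_matrix(
                (np.ones(len(self.edges)),
                 (self.edges[:, 0], self.edges[:, 1])), shape=(n, n))
            _, self.component = connected_components(adj, directed=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cell_index)

    def laplacian(self) -> csc_matrix:
        """Conductance Laplacian (edge conductance = 1 / edge resistance)."""
        n = self.n_nodes
        i, j = self.edges[:, 0], self.edges[:, 1]
        g = 1.0 / self.resistances
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-g, -g, g, g])
        return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()

    def node_of_cell(self, row: int, col: int) -> int:
        hit = np.flatnonzero((self.cell_index[:, 0] == row) &
                             (self.cell_index[:, 1] == col))
        if len(hit) == 0:
            raise KeyError(f"cell ({row}, {col}) is not in the graph")
        return int(hit[0])


@dataclass
class CircuitResult:
    """Pairwise effective resistance/conductance and the current map."""

    node_ids: np.ndarray
    R: np.ndarray                   # symmetric; inf across components
    cumulative_current: Grid | None = None
    pair_currents: dict | None = None
    n_pairs: int = 0

    @property
    def G(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            g = 1.0 / self.R
        g[~np.isfinite(self.R)] = 0.0
        np.fill_diagonal(g, 0.0)
        return g


def build_graph(resistance: CumulativeResistance | Grid) -> ResistanceGraph:
    """Resistor network from a resistance raster (8-neighbour connectivity).

    Edge resistance between neighbouring cells is the mean of their cell
    resistances, multiplied by √2 for diagonal neighbours (the longer
    traverse); nodata cells are excluded.
    """
    grid = resistance.grid if isinstance(resistance, CumulativeResistance) \
        else resistance
    r = np.asarray(grid.data, dtype=float)
    valid = ~grid.nodata_mask & np.isfinite(r)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    nr, nc = grid.shape
    node_id = np.full((nr, nc), -1, dtype=int)
    cells = np.argwhere(valid)
    node_id[valid] = np.arange(len(cells))

    ei, ej, er = [], [], []
    # scan only the 4 forward offsets so each edge appears once
    for dr, dc in [(0, 1), (1, -1), (1, 0), (1, 1)]:
        rs = slice(max(dr, 0), nr + min(dr, 0))
        cs = slice(max(dc, 0), nc + min(dc, 0))
        rd = slice(max(-dr, 0), nr + min(-dr, 0))
        cd = slice(max(-dc, 0), nc + min(-dc, 0))
        ok = valid[rd, cd] & valid[rs, cs]
        a = node_id[rd, cd][ok]
        b = node_id[rs, cs][ok]
        res = 0.5 * (r[rd, cd][ok] + r[rs, cs][ok])
        if dr != 0 and dc != 0:
            res = res * np.sqrt(2.0)
        ei.append(a)
        ej.append(b)
        er.append(res)
    edges = np.column_stack([np.concatenate(ei), np.concatenate(ej)])
    edges = np.sort(edges, axis=1)
    return ResistanceGraph(cells, edges, np.concatenate(er), grid=grid)


def _node_currents(graph: ResistanceGraph, v: np.ndarray,
                   source: int, target: int, injection: float) -> np.ndarray:
    """Current density per node: half the summed |incident branch currents|,
    with source and target pinned at the injection."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    branch = (v[i] - v[j]) / graph.resistances
    node = np.zeros(graph.n_nodes)
    np.add.at(node, i, np.abs(branch))
    np.add.at(node, j, np.abs(branch))
    node *= 0.5
    node[source] = injection
    node[target] = injection
    return node


def solve_pair(graph: ResistanceGraph, source: int, target: int,
               injection: float = 1.0):
    """Potentials, branch/node currents, and R̂ for one focal pair.

    Solves ``L v = b`` with +injection at the source, −injection at the
    target, and the target grounded. A disconnected pair is signalled as
    ``R = inf`` with zero currents, not an exception.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if graph.component[source] != graph.component[target]:
        n = graph.n_nodes
        return (np.full(n, np.nan), np.zeros(len(graph.edges)),
                np.zeros(n), np.inf)
    comp = graph.component == graph.component[source]
    idx = np.flatnonzero(comp)
    pos = {g: k for k, g in enumerate(idx)}
    L = graph.laplacian()[np.ix_(idx, idx)].tocsc()
    s, t = pos[source], pos[target]
    keep = np.arange(len(idx)) != t  # ground the target
    Lr = L[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
    b = np.zeros(len(idx))
    b[s] = injection
    from scipy.sparse.linalg import spsolve
    v_red = spsolve(Lr.tocsc(), b[keep])
    v_comp = np.zeros(len(idx))
    v_comp[keep] = v_red
    v = np.full(graph.n_nodes, np.nan)
    v[idx] = v_comp
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    with np.errstate(invalid="ignore"):
        branch = np.where(comp[i] & comp[j],
                          (np.nan_to_num(v[i]) - np.nan_to_num(v[j]))
                          / graph.resistances, 0.0)
    node = _node_currents(graph, np.nan_to_num(v), source, target, injection)
    node[~comp] = 0.0
    R = (v[source] - v[target]) / injection
    return v, branch, node, float(R)


def pairwise_all(graph: ResistanceGraph, nodes: FocalNodeSet,
                 keep_pair_maps: bool = False) -> CircuitResult:
    """Solve every unordered focal-node pair and accumulate current.

    Focal nodes must sit on valid graph cells (snap first). Per component,
    the grounded Laplacian is factorised once and reused for all pairs in it.
    The cumulative current grid is the unnormalised sum of the per-pair
    node-current maps under unit injection.
    """
    tbl = nodes.table
    if "row" not in tbl.columns:
        raise ValueError("nodes are not snapped to the grid (no row/col)")
    gidx = []
    for _, rec in tbl.iterrows():
        gidx.append(graph.node_of_cell(int(rec["row"]), int(rec["col"])))
    gidx = np.array(gidx)
    n = len(gidx)
    if n < 2:
        raise ValueError("need at least 2 focal nodes")
    R = np.zeros((n, n))
    cum = np.zeros(graph.n_nodes)
    pair_maps = {} if keep_pair_maps else None

    # factorise once per component that hosts >= 2 focal nodes
    comps = graph.component[gidx]
    i_idx, j_idx = graph.edges[:, 0], graph.edges[:, 1]
    n_pairs = 0
    for comp_label in np.unique(comps):
        members = np.flatnonzero(comps == comp_label)
        idx = np.flatnonzero(graph.component == comp_label)
        pos = np.full(graph.n_nodes, -1)
        pos[idx] = np.arange(len(idx))
        if len(members) >= 2 and len(idx) >= 2:
            L = graph.laplacian()[np.ix_(idx, idx)].tocsc()
            ground = len(idx) - 1
            keep = np.flatnonzero(np.arange(len(idx)) != ground)
            solve = factorized(L[np.ix_(keep, keep)])
        else:
            solve = None
        for a_i, b_i in combinations(members, 2):
            sa, tb = gidx[a_i], gidx[b_i]
            s, t = pos[sa], pos[tb]
            b_vec = np.zeros(len(idx))
            b_vec[s] = 1.0
            b_vec[t] = -1.0
            v_red = solve(b_vec[keep])
            v_comp = np.zeros(len(idx))
            v_comp[keep] = v_red
            R[a_i, b_i] = R[b_i, a_i] = v_comp[s] - v_comp[t]
            v_full = np.zeros(graph.n_nodes)
            v_full[idx] = v_comp
            node = _node_currents(graph, v_full, sa, tb, 1.0)
            node[graph.component != comp_label] = 0.0
            cum += node
            n_pairs += 1
            if keep_pair_maps:
                pair_maps[(int(tbl["node_id"].iloc[a_i]),
                           int(tbl["node_id"].iloc[b_i]))] = node
    # cross-component pairs are disconnected
    for a_i, b_i in combinations(range(n), 2):
        if comps[a_i] != comps[b_i]:
            R[a_i, b_i] = R[b_i, a_i] = np.inf

    cum_grid = None
    if graph.grid is not None:
        arr = np.zeros(graph.grid.shape)
        arr[tuple(graph.cell_index.T)] = cum
        cum_grid = graph.grid.like(arr)
    return CircuitResult(node_ids=tbl["node_id"].to_numpy(), R=R,
                         cumulative_current=cum_grid, pair_currents=pair_maps,
                         n_pairs=n_pairs)


def effective_conductance(result: CircuitResult) -> np.ndarray:
    """Ĝ = 1/R̂ per pair; zero for disconnected pairs."""
    return result.G
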