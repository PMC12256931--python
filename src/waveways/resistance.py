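"""Expert-parameterised resistance surface for bear movement.

Three habitat variables are scored on an ordinal 1 (very low) to 6 (very
high) resistance scale:

* terrain ruggedness (TRI, Riley neighbourhood form), classed at natural
  breaks in the study DEM;
* landcover — mature forest, bryoid/shrub/herb, and barren rock are fully
  permeable (1); regenerating stands 10-75 years post-harvest, in the
  stem-exclusion stage, are a moderate impediment (3); snow and ice are
  near-barriers (6);
* open water by distance to shore — under 1 km is a swimmable crossing (3),
  1-3 km strongly resists movement (5), beyond 3 km is a near-barrier (6).

The layers are summed equally (land cells carry terrain + landcover, water
cells terrain + water) and the summed surface is rescaled onto a 1-10
cumulative resistance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .grid import Grid
from .synthetic import LANDCOVER_CODES

__all__ = [
    "ClassificationScheme", "ResistanceLayer", "CumulativeResistance",
    "TRI_SCHEME", "WATER_SCHEME", "LANDCOVER_RESISTANCE",
    "terrain_ruggedness_index", "jenks_breaks", "classify_continuous",
    "classify_landcover", "distance_to_shore", "classify_water",
    "combine_layers", "clip_with_buffer",
]


@dataclass
class ClassificationScheme:
    """Ordered bins mapping a continuous variable to resistance classes.

    ``bins`` is a list of ``(lower, upper, resistance, label)``; bins must be
    ordered and non-overlapping, resistance integers in [1, 6]. Values below
    the first lower bound take the first class, values above the last upper
    bound the last class (the printed extremes are the study area's observed
    range, not hard limits).
    """

    bins: list[tuple[float, float, int, str]]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("empty scheme")
        prev_hi = -np.inf
        for lo, hi, r, _ in self.bins:
            if lo > hi or lo < prev_hi:
                raise ValueError("bins must be ordered and non-overlapping")
            prev_hi = hi
            if not (isinstance(r, (int, np.integer)) and 1 <= r <= 6):
                raise ValueError("resistance values must be integers in [1,6]")

    def classify(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.full(values.shape, self.bins[0][2], dtype=float)
        for lo, hi, r, _ in self.bins:
            out[(values >= lo) & (values <= hi)] = r
        out[values > self.bins[-1][1]] = self.bins[-1][2]
        out[values < self.bins[0][0]] = self.bins[0][2]
        return out


#: TRI classes at the study's natural breaks.
TRI_SCHEME = ClassificationScheme([
    (1, 25, 1, "very low"),
    (25, 50, 2, "low"),
    (50, 88, 3, "low-medium"),
    (88, 139, 4, "medium-high"),
    (139, 230, 5, "high"),
    (230, 271, 6, "very high"),
])

#: Open-water classes by distance to shore (metres).
WATER_SCHEME = ClassificationScheme([
    (0, 1000, 3, "low-medium"),
    (1000, 3000, 5, "high"),
    (3000, np.inf, 6, "very high"),
])

#: Landcover class -> resistance. Stands harvested < 10 years ago are scored
#: like the open bryoid/shrub class (early-seral, forage-rich open ground).
LANDCOVER_RESISTANCE = {
    "mature_forest": 1,
    "bryoid_shrub_herb": 1,
    "barren_rock": 1,
    "regenerating_forest": 3,
    "snow_ice": 6,
}
EARLY_SERAL_RESISTANCE = 1
REGEN_AGE_RANGE = (10.0, 75.0)


@dataclass
class ResistanceLayer:
    """One habitat variable's per-cell resistance on its domain."""

    grid: Grid
    provenance: str  # tri | landcover | water

    def __post_init__(self) -> None:
        vals = self.grid.valid_values()
        if len(vals) and (vals.min() < 1 or vals.max() > 6):
            raise ValueError("layer resistance outside [1, 6]")


@dataclass
class CumulativeResistance:
    """Combined surface rescaled onto the 1-10 cumulative scale."""

    grid: Grid
    scale_min: float = 1.0
    scale_max: float = 10.0
    raw: Grid = field(default=None, repr=False)  # type: ignore[assignment]


def terrain_ruggedness_index(elevation: Grid) -> Grid:
    """TRI: root of the summed squared elevation differences to 8 neighbours.

    ``TRI(c) = sqrt(sum_n (z_n - z_c)^2)`` over the 8-neighbourhood; edge
    cells use the neighbours they have. Computed over the full grid (water
    included; flat water contributes nothing inland of the coast rim).
    """
    z = np.asarray(elevation.data, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation grid must be at least 3x3")
    acc = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(z, np.nan)
            rs = slice(max(dr, 0), z.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), z.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), z.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), z.shape[1] + min(-dc, 0))
            shifted[rd, cd] = z[rs, cs]
            diff = shifted - z
            acc += np.where(np.isnan(diff), 0.0, diff ** 2)
    return elevation.like(np.sqrt(acc))


def jenks_breaks(values, k: int) -> list[float]:
    """Fisher-Jenks natural breaks: k classes minimising within-class SSD.

    Returns ``k + 1`` ordered break values ``[min, b1, ..., min of last
    class... max]`` — the conventional inclusive break list. Exact dynamic
    programme, deterministic; O(k n^2).
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(vals)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if len(np.unique(vals)) < k:
        raise ValueError("fewer distinct values than classes")
    # prefix sums for O(1) within-class SSD
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cs2 = np.concatenate([[0.0], np.cumsum(vals ** 2)])

    def ssd(i, j):  # values[i..j] inclusive
        m = j - i + 1
        s = cs[j + 1] - cs[i]
        return (cs2[j + 1] - cs2[i]) - s * s / m

    cost = np.full((k + 1, n), np.inf)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        cost[1, j] = ssd(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, n):
            for i in range(c - 1, j + 1):
                cand = cost[c - 1, i - 1] + ssd(i, j)
                if cand < cost[c, j]:
                    cost[c, j] = cand
                    back[c, j] = i
    breaks = [vals[-1]]
    j = n - 1
    for c in range(k, 1, -1):
        i = back[c, j]
        breaks.append(vals[i - 1])
        j = i - 1
    breaks.append(vals[0])
    return breaks[::-1]


def classify_continuous(grid: Grid, scheme: ClassificationScheme
                        ) -> ResistanceLayer:
    """Assign each cell its bin's resistance; nodata propagates."""
    out = scheme.classify(grid.data)
    out = np.where(grid.nodata_mask, np.nan, out)
    return ResistanceLayer(grid.like(out), provenance="tri")


def classify_landcover(landcover: Grid, stand_age_years: Grid
                       ) -> ResistanceLayer:
    """Landcover resistance on land; water is nodata on this layer.

    Forest resistance depends on stand age: over 75 years (or never
    harvested) counts as mature (1); 10-75 years is regenerating (3); under
    10 years is early-seral open ground (1).
    """
    code_to_name = {v: k for k, v in LANDCOVER_CODES.items()}
    codes = np.asarray(landcover.data, dtype=int)
    known = np.isin(codes, list(code_to_name))
    if not known.all():
        bad = np.unique(codes[~known])
        raise ValueError(f"unknown landcover categories: {bad.tolist()}")
    out = np.full(codes.shape, np.nan)
    age = np.asarray(stand_age_years.data, dtype=float)
    lo, hi = REGEN_AGE_RANGE
    for code, name in code_to_name.items():
        sel = codes == code
        if name == "water/none":
            continue
        if name in ("mature_forest", "regenerating_forest"):
            a = np.where(np.isnan(age), np.inf, age)
            out[sel & (a > hi)] = LANDCOVER_RESISTANCE["mature_forest"]
            out[sel & (a >= lo) & (a <= hi)] = \
                LANDCOVER_RESISTANCE["regenerating_forest"]
            out[sel & (a < lo)] = EARLY_SERAL_RESISTANCE
        else:
            out[sel] = LANDCOVER_RESISTANCE[name]
    mask = landcover.nodata_mask | (codes == LANDCOVER_CODES["water/none"])
    return ResistanceLayer(landcover.like(out, mask=mask),
                           provenance="landcover")


def distance_to_shore(water_mask: Grid) -> Grid:
    """Euclidean distance (m) from each water cell centre to the nearest
    land cell centre; 0 on land."""
    water = np.asarray(water_mask.data, dtype=bool)
    if (~water).sum() == 0:
        raise ValueError("all-water mask: no shore to measure from")
    d = ndimage.distance_transform_edt(
        water, sampling=water_mask.cell_size)
    return water_mask.like(d)


def classify_water(distance: Grid, water_mask: Grid) -> ResistanceLayer:
    """Water resistance by distance to shore; land is nodata on this layer."""
    water = np.asarray(water_mask.data, dtype=bool)
    out = WATER_SCHEME.classify(distance.data)
    out = np.where(water, out, np.nan)
    return ResistanceLayer(distance.like(out, mask=~water),
                           provenance="water")


def combine_layers(tri: ResistanceLayer, landcover: ResistanceLayer,
                   water: ResistanceLayer) -> CumulativeResistance:
    """Sum the layers equally and rescale onto the 1-10 cumulative scale.

    Each cell sums the layers defined there (land: terrain + landcover;
    water: terrain + water). The raw sum is mapped affinely so its minimum
    is 1 and maximum 10; a constant raw field maps to uniform 1.
    """
    grids = [tri.grid, landcover.grid, water.grid]
    shape = grids[0].shape
    for g in grids[1:]:
        if g.shape != shape:
            raise ValueError("layers are not co-registered")
    raw = np.zeros(shape)
    defined = np.zeros(shape, dtype=bool)
    for g in grids:
        ok = ~g.nodata_mask & np.isfinite(np.asarray(g.data, dtype=float))
        raw[ok] += g.data[ok]
        defined |= ok
    if not defined.any():
        raise ValueError("no cell has any defined layer")
    vals = raw[defined]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        final = 1.0 + 9.0 * (raw - lo) / (hi - lo)
    else:
        final = np.ones(shape)
    final[~defined] = np.nan
    out = grids[0].like(final, mask=~defined)
    raw_grid = grids[0].like(raw.copy(), mask=~defined)
    return CumulativeResistance(out, raw=raw_grid)


def clip_with_buffer(grid: Grid, boundary: BaseGeometry,
                     buffer_m: float = 10000.0) -> Grid:
    """Clip to the study boundary plus an edge-effect buffer.

    Cells whose centres fall outside ``boundary`` buffered by ``buffer_m``
    become nodata, and the grid is cropped to the buffered bounding box.
    """
    buffered = boundary.buffer(buffer_m) if buffer_m else boundary
    nr, nc = grid.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    xs, ys = grid.cell_center(rows.ravel(), cols.ravel())
    prepared = prep(buffered)
    inside = np.array([prepared.contains(Point(x, y))
                       for x, y in zip(xs, ys)]).reshape(nr, nc)
    if not inside.any():
        raise ValueError("buffered boundary does not intersect the grid")
    keep_r = np.flatnonzero(inside.any(axis=1))
    keep_c = np.flatnonzero(inside.any(axis=0))
    r0, r1 = keep_r[0], keep_r[-1] + 1
    c0, c1 = keep_c[0], keep_c[-1] + 1
    data = np.asarray(grid.data, dtype=float)[r0:r1, c0:c1].copy()
    mask = (grid.nodata_mask | ~inside)[r0:r1, c0:c1].copy()
    data[mask] = np.nan
    x0, ytop = grid.origin
    origin = (x0 + c0 * grid.cell_size, ytop - r0 * grid.cell_size)
    return Grid(data, grid.cell_size, origin, grid.crs, mask)
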