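"""Synthetic coastal landscapes, sampling designs, and movement data.

The study system is a fjordic seascape: islands and mainland valleys, salmon
streams draining to the coast, rugged terrain, patches of regenerating forest
from logging, and snow/ice at high elevation. This module fabricates every
input the connectivity pipeline consumes so the whole analysis is testable
offline:

* terrain — spectrally synthesised, spatially autocorrelated elevation;
* a land/water mask with islands, and a five-class landcover mosaic;
* branching streams carrying species-labelled spawning reaches;
* a jittered grid of hair-snag sites;
* noninvasive genetic-recapture detections from a half-normal encounter model;
* Bernoulli site-pair transit outcomes whose log-odds are linear in effective
  conductance and inter-site distance (the structure the validation module
  fits).

Every generator is deterministic under a fixed seed; a single master seed
fans out to sub-generators by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .grid import Grid
from .nodes import FocalNodeSet

__all__ = [
    "LandscapeConfig", "DetectionModel", "TransitSimModel", "StreamNetwork",
    "LANDCOVER_CODES", "generate_elevation", "generate_land_mask",
    "generate_landcover", "generate_hydrology", "generate_snag_sites",
    "simulate_detections", "simulate_transits", "calibrate_intercept",
]

# Integer codes for the landcover raster. Water is code 0 and is excluded
# from the landcover resistance layer (it gets the water layer instead).
LANDCOVER_CODES = {
    "water/none": 0,
    "mature_forest": 1,
    "bryoid_shrub_herb": 2,
    "barren_rock": 3,
    "regenerating_forest": 4,
    "snow_ice": 5,
}

# fixed seed offsets so one master seed drives independent sub-streams
_OFF_ELEV, _OFF_LAND, _OFF_COVER, _OFF_HYDRO = 11, 23, 37, 51
_OFF_SITES, _OFF_DETECT, _OFF_TRANSIT = 67, 83, 97


@dataclass
class LandscapeConfig:
    """Parameters of a synthetic study landscape.

    ``extent_m`` is (width, height); ``cell_size_m`` defaults to the 150 m
    working resolution; ``ruggedness_scale`` is the total relief in metres.
    """

    extent_m: tuple[float, float] = (9000.0, 9000.0)
    cell_size_m: float = 150.0
    seed: int = 0
    land_fraction: float = 0.6
    n_streams: int = 6
    reaches_per_stream: int = 2
    species_labels: tuple[str, ...] = ("chum", "pink", "coho")
    ruggedness_scale: float = 800.0
    regen_fraction: float = 0.15
    snowice_fraction: float = 0.05

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0 or self.cell_size_m <= 0:
            raise ValueError("extent and cell size must be positive")
        if abs(w / self.cell_size_m - round(w / self.cell_size_m)) > 1e-9 or \
                abs(h / self.cell_size_m - round(h / self.cell_size_m)) > 1e-9:
            raise ValueError("extent must divide into whole cells")
        for name in ("land_fraction", "regen_fraction", "snowice_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.regen_fraction + self.snowice_fraction > 1.0:
            raise ValueError("landcover fractions sum to more than 1")
        if not 1 <= len(self.species_labels) <= 5:
            raise ValueError("1-5 species labels required")

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.extent_m
        return int(round(h / self.cell_size_m)), int(round(w / self.cell_size_m))


@dataclass
class DetectionModel:
    """Half-normal encounter model for baited hair-snag sampling.

    Each individual has a home-range centre; the per-session probability of
    leaving hair at a site ``d`` metres away is ``p0 * exp(-d^2 / (2 sigma^2))``
    — the standard spatial capture–recapture encounter form. Sites are
    revisited ``sessions_per_year`` times (default 2) each sampling season.
    """

    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"grizzly": 66, "black": 199})
    home_range_sigma_m: float = 5170.0
    baseline_detection_prob: float = 0.3
    n_years: int = 5
    sessions_per_year: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_detection_prob <= 1.0:
            raise ValueError("baseline_detection_prob must be in [0, 1]")
        if self.sessions_per_year < 1:
            raise ValueError("sessions_per_year must be >= 1")
        if self.home_range_sigma_m < 0:
            raise ValueError("home_range_sigma_m must be non-negative")


@dataclass
class TransitSimModel:
    """Log-odds coefficients for Bernoulli site-pair transit outcomes.

    ``logit P(transit) = beta0 + beta_G * z(G) + beta_d * z(d)`` where ``G`` is
    effective conductance, ``d`` Euclidean distance, and ``z`` standardisation
    (applied when ``standardize`` is set).
    """

    beta0: float = -3.66
    beta_G: float = float(np.log(1.66))
    beta_d: float = float(np.log(0.36))
    standardize: bool = True

    def __post_init__(self) -> None:
        for b in (self.beta0, self.beta_G, self.beta_d):
            if not np.isfinite(b):
                raise ValueError("coefficients must be finite")


@dataclass
class StreamNetwork:
    """Stream polylines and species-labelled spawning reaches.

    ``streams``: watershed_code, geometry. ``reaches``: watershed_code,
    species, length_m, geometry (a sub-polyline of its stream).
    """

    streams: pd.DataFrame
    reaches: pd.DataFrame


# ---------------------------------------------------------------------------
# terrain and landcover
# ---------------------------------------------------------------------------

def _spectral_field(shape: tuple[int, int], rng: np.random.Generator,
                    beta: float = 1.8) -> np.ndarray:
    """Spatially autocorrelated Gaussian field via power-law spectral shaping."""
    nr, nc = shape
    white = rng.standard_normal((nr, nc))
    spec = np.fft.rfft2(white)
    ky = np.fft.fftfreq(nr)[:, None]
    kx = np.fft.rfftfreq(nc)[None, :]
    k = np.hypot(ky, kx)
    k[0, 0] = np.inf  # kill the DC term
    spec *= k ** (-beta)
    out = np.fft.irfft2(spec, s=(nr, nc))
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_elevation(config: LandscapeConfig) -> Grid:
    """Continuous, autocorrelated elevation spanning ≈ [0, ruggedness_scale].

    Water cells (below the sea-level quantile implied by ``land_fraction``)
    are clamped to 0 so the coastline is a contour of the field.
    """
    shape = config.shape
    rng = np.random.default_rng(config.seed + _OFF_ELEV)
    if config.ruggedness_scale == 0:
        return Grid(np.zeros(shape), config.cell_size_m)
    f = _spectral_field(shape, rng)
    f = f - f.min()
    if f.max() > 0:
        f = f / f.max()
    sea = np.quantile(f, 1.0 - config.land_fraction) if \
        config.land_fraction < 1.0 else 0.0
    elev = np.clip(f - sea, 0.0, None)
    if elev.max() > 0:
        elev = elev / elev.max() * config.ruggedness_scale
    return Grid(elev, config.cell_size_m)


def generate_land_mask(elevation: Grid, config: LandscapeConfig) -> Grid:
    """Boolean land grid (True = land) from the elevation sea level."""
    if config.land_fraction >= 1.0:
        land = np.ones(elevation.shape, dtype=bool)
    elif config.land_fraction <= 0.0:
        land = np.zeros(elevation.shape, dtype=bool)
    else:
        land = elevation.data > 0
    return elevation.like(land, mask=np.zeros(elevation.shape, dtype=bool))


def generate_landcover(elevation: Grid, config: LandscapeConfig
                       ) -> tuple[Grid, Grid]:
    """Categorical landcover plus a stand-age grid.

    Snow/ice occupies the top ``snowice_fraction`` elevation quantile of land;
    regenerating forest forms contiguous patches (thresholded autocorrelated
    noise) covering ≈ ``regen_fraction`` of land; barren rock sits on a high
    band below the snowline; the rest splits between mature forest and
    bryoid/shrub/herb openings. Water cells take code 0 and are excluded from
    the landcover resistance layer. Stand age is 100+ years for mature forest
    and uniform 10-75 for regenerating stands.
    """
    rng = np.random.default_rng(config.seed + _OFF_COVER)
    land = generate_land_mask(elevation, config).data
    codes = np.zeros(elevation.shape, dtype=int)  # water/none
    n_land = int(land.sum())
    age = np.full(elevation.shape, 120.0)
    if n_land == 0:
        return elevation.like(codes), elevation.like(age)

    z_land = elevation.data[land]
    codes[land] = LANDCOVER_CODES["mature_forest"]

    if config.snowice_fraction > 0:
        snow_thr = np.quantile(z_land, 1.0 - config.snowice_fraction)
        snow = land & (elevation.data >= snow_thr)
        codes[snow] = LANDCOVER_CODES["snow_ice"]
    else:
        snow = np.zeros_like(land)

    # barren band just below the snowline (upper ~10% of remaining land)
    rest = land & ~snow
    if rest.any():
        barren_thr = np.quantile(elevation.data[rest], 0.90)
        barren = rest & (elevation.data >= barren_thr)
        codes[barren] = LANDCOVER_CODES["barren_rock"]
        rest = rest & ~barren

    # shrub/herb openings from autocorrelated noise (~15% of the remainder)
    noise = _spectral_field(elevation.shape, rng, beta=1.5)
    if rest.any():
        shrub_thr = np.quantile(noise[rest], 0.85)
        shrub = rest & (noise >= shrub_thr)
        codes[shrub] = LANDCOVER_CODES["bryoid_shrub_herb"]
        rest = rest & ~shrub

    if config.regen_fraction > 0 and rest.any():
        regen_field = _spectral_field(elevation.shape, rng, beta=2.2)
        # threshold chosen on land so patches cover ~regen_fraction of land
        target = config.regen_fraction * n_land
        frac_of_rest = min(1.0, target / max(rest.sum(), 1))
        thr = np.quantile(regen_field[rest], 1.0 - frac_of_rest)
        regen = rest & (regen_field >= thr)
        codes[regen] = LANDCOVER_CODES["regenerating_forest"]
        age[regen] = rng.uniform(10.0, 75.0, size=int(regen.sum()))

    age[~land] = np.nan
    cover = elevation.like(codes)
    cover.nodata_mask = np.zeros(elevation.shape, dtype=bool)
    return cover, elevation.like(age, mask=~land)


# ---------------------------------------------------------------------------
# hydrology
# ---------------------------------------------------------------------------

def _truncated_lognormal_lengths(rng: np.random.Generator, size: int,
                                 mean_m: float = 1700.0,
                                 lo: float = 19.0, hi: float = 11300.0,
                                 sigma: float = 1.0) -> np.ndarray:
    """Reach lengths: log-normal truncated to the observed [19 m, 11.3 km].

    ``mu`` is set so the *truncated* mean is ≈ ``mean_m`` (solved once by
    bisection on the analytic truncated-lognormal mean).
    """
    from scipy.stats import norm

    def trunc_mean(mu):
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        z = norm.cdf(b) - norm.cdf(a)
        if z <= 0:
            return np.inf
        return np.exp(mu + sigma ** 2 / 2) * \
            (norm.cdf(b - sigma) - norm.cdf(a - sigma)) / z

    lo_mu, hi_mu = np.log(lo), np.log(hi)
    for _ in range(80):
        mid = 0.5 * (lo_mu + hi_mu)
        if trunc_mean(mid) < mean_m:
            lo_mu = mid
        else:
            hi_mu = mid
    mu = 0.5 * (lo_mu + hi_mu)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size * 2)
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


def _descend_to_coast(start: tuple[int, int], dist_to_water: np.ndarray,
                      elevation: np.ndarray) -> list[tuple[int, int]]:
    """Greedy 8-neighbour walk decreasing distance-to-water until the coast."""
    nr, nc = dist_to_water.shape
    path = [start]
    r, c = start
    while dist_to_water[r, c] > 0:
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and \
                        dist_to_water[rr, cc] < dist_to_water[r, c]:
                    key = (dist_to_water[rr, cc], elevation[rr, cc], rr, cc)
                    if best is None or key < best[0]:
                        best = (key, rr, cc)
        if best is None:
            break
        r, c = best[1], best[2]
        if dist_to_water[r, c] == 0:
            break  # next step would enter the sea; end at the coastal rim
        path.append((r, c))
    return path


def generate_hydrology(elevation: Grid, config: LandscapeConfig
                       ) -> StreamNetwork:
    """Streams from interior high ground to the coast, with species reaches.

    Each stream starts at a high-elevation interior cell and follows a greedy
    path of decreasing distance-to-water (ties broken downhill) until it meets
    the sea, so every stream reaches the coast and stays on land. Streams get
    unique watershed codes; each carries 1..len(species_labels) species, and
    each species' spawning reach is the sub-polyline extending upstream from
    the mouth by a truncated log-normal length.
    """
    land = generate_land_mask(elevation, config).data
    if not land.any():
        raise ValueError("no land to place streams on")
    rng = np.random.default_rng(config.seed + _OFF_HYDRO)
    if land.all():
        # no coast: distance to the grid edge stands in for distance to water
        dist = ndimage.distance_transform_edt(
            np.pad(land, 1, constant_values=False))[1:-1, 1:-1]
    else:
        dist = ndimage.distance_transform_edt(land)

    # candidate headwaters: upper elevation quartile of land, sampled
    z = elevation.data
    land_idx = np.argwhere(land)
    thr = np.quantile(z[land], 0.75)
    heads = land_idx[z[land_idx[:, 0], land_idx[:, 1]] >= thr]
    if len(heads) == 0:
        heads = land_idx
    order = rng.permutation(len(heads))

    streams, reaches = [], []
    code = 0
    for idx in order:
        if code >= config.n_streams:
            break
        r0, c0 = heads[idx]
        cells = _descend_to_coast((r0, c0), dist, z)
        if len(cells) < 3:
            continue
        xs, ys = elevation.cell_center(np.array([p[0] for p in cells]),
                                       np.array([p[1] for p in cells]))
        line = LineString(np.column_stack([xs, ys]))
        if line.length == 0:
            continue
        code += 1
        wcode = f"WS{code:03d}"
        streams.append({"watershed_code": wcode, "geometry": line})
        n_sp = int(rng.integers(1, min(config.reaches_per_stream,
                                       len(config.species_labels)) + 1))
        species = rng.choice(config.species_labels, size=n_sp, replace=False)
        lengths = _truncated_lognormal_lengths(rng, n_sp)
        for sp, length in zip(species, lengths):
            length = min(length, line.length)
            # reach runs upstream from the mouth (line end is the coast)
            start = max(line.length - length, 0.0)
            pts = [line.interpolate(start)]
            n_seg = max(int(np.ceil(length / config.cell_size_m)), 1)
            for k in range(1, n_seg + 1):
                pts.append(line.interpolate(start + length * k / n_seg))
            geom = LineString(pts)
            reaches.append({"watershed_code": wcode, "species": str(sp),
                            "length_m": geom.length, "geometry": geom})
    if not streams:
        raise ValueError("could not route any stream to the coast")
    return StreamNetwork(pd.DataFrame(streams), pd.DataFrame(reaches))


# ---------------------------------------------------------------------------
# sampling design and movement data
# ---------------------------------------------------------------------------

def generate_snag_sites(config: LandscapeConfig, n_sites: int,
                        land: Grid | None = None,
                        elevation: Grid | None = None) -> FocalNodeSet:
    """Jittered grid of hair-snag sites on land, evenly spaced.

    Sites are laid on a regular grid covering the extent, jittered by up to a
    quarter of the grid spacing, and snapped to the nearest land cell centre.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if land is None:
        if elevation is None:
            elevation = generate_elevation(config)
        land = generate_land_mask(elevation, config)
    land_rc = np.argwhere(land.data)
    if len(land_rc) < n_sites:
        raise ValueError("more sites requested than land cells")
    rng = np.random.default_rng(config.seed + _OFF_SITES)
    w, h = config.extent_m
    aspect = w / h
    nx = max(int(np.ceil(np.sqrt(n_sites * aspect))), 1)
    ny = int(np.ceil(n_sites / nx))
    sx, sy = w / nx, h / ny
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * sx, (np.arange(ny) + 0.5) * sy)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts += rng.uniform(-0.25, 0.25, pts.shape) * np.array([sx, sy])
    # snap to nearest land cell centre
    lx, ly = land.cell_center(land_rc[:, 0], land_rc[:, 1])
    land_xy = np.column_stack([lx, ly])
    from scipy.spatial import cKDTree
    tree = cKDTree(land_xy)
    x0, ytop = land.origin
    pts_xy = np.column_stack([x0 + pts[:, 0], ytop - pts[:, 1]])
    _, nearest = tree.query(pts_xy)
    # deduplicate while preserving grid order, then take the first n_sites
    seen, chosen = set(), []
    for i in nearest:
        if i not in seen:
            seen.add(i)
            chosen.append(i)
    if len(chosen) < n_sites:
        for i in rng.permutation(len(land_xy)):
            if i not in seen:
                seen.add(i)
                chosen.append(i)
            if len(chosen) == n_sites:
                break
    chosen = np.array(chosen[:n_sites])
    return FocalNodeSet.from_points(land_xy[chosen], source="snag_site")


def simulate_detections(sites: FocalNodeSet, model: DetectionModel,
                        seed: int, config: LandscapeConfig | None = None,
                        land: Grid | None = None) -> pd.DataFrame:
    """Detection histories from the half-normal encounter model.

    Individuals get home-range centres uniform on land (or on the sites'
    bounding box when no land grid is supplied); each site × year × session,
    individual *i* is detected with probability ``p0 exp(-d_i^2 / 2 sigma^2)``.
    Returns rows (individual_id, species, site_id, year, session).
    """
    rng = np.random.default_rng(seed + _OFF_DETECT)
    xy = sites.xy
    if land is not None:
        rc = np.argwhere(land.data)
        cx, cy = land.cell_center(rc[:, 0], rc[:, 1])
        centre_pool = np.column_stack([cx, cy])
    else:
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        centre_pool = None

    rows = []
    for species, n_ind in model.n_individuals.items():
        for k in range(n_ind):
            ind_id = f"{species}_{k:04d}"
            if centre_pool is not None:
                centre = centre_pool[rng.integers(len(centre_pool))]
            else:
                centre = rng.uniform(lo, hi)
            d2 = ((xy - centre) ** 2).sum(axis=1)
            if model.home_range_sigma_m == 0:
                p = np.where(d2 == 0, model.baseline_detection_prob, 0.0)
            elif np.isinf(model.home_range_sigma_m):
                p = np.full(len(xy), model.baseline_detection_prob)
            else:
                p = model.baseline_detection_prob * \
                    np.exp(-d2 / (2 * model.home_range_sigma_m ** 2))
            for year in range(model.n_years):
                for session in range(model.sessions_per_year):
                    hit = rng.random(len(xy)) < p
                    for s in np.flatnonzero(hit):
                        rows.append((ind_id, species,
                                     sites.table["node_id"].iloc[s],
                                     2015 + year, session + 1))
    return pd.DataFrame(rows, columns=["individual_id", "species", "site_id",
                                       "year", "session"])


def calibrate_intercept(pairs: pd.DataFrame, model: TransitSimModel,
                        target_rate: float) -> float:
    """Intercept giving an expected transit rate of ``target_rate``.

    Solves ``mean(expit(beta0 + beta_G z(G) + beta_d z(d))) = target`` by
    bisection on ``beta0``, holding the slope coefficients fixed. Used to pin
    the simulation's base rate (e.g., to the sparse observed 54/2145) for a
    given pair design.
    """
    from scipy.special import expit

    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must be in (0, 1)")
    g = np.asarray(pairs["G"], dtype=float)
    d = np.asarray(pairs["distance_m"], dtype=float)
    if model.standardize:
        g = (g - g.mean()) / g.std()
        d = (d - d.mean()) / d.std()
    lin = model.beta_G * g + model.beta_d * d
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + lin).mean() < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_transits(pairs: pd.DataFrame, model: TransitSimModel,
                      seed: int) -> pd.DataFrame:
    """Bernoulli transit outcomes for site pairs.

    ``pairs`` needs columns ``G`` (effective conductance) and ``distance_m``;
    the returned copy gains a ``transited`` 0/1 column drawn from
    ``Bernoulli(expit(beta0 + beta_G z(G) + beta_d z(d)))``.
    """
    from scipy.special import expit

    g = np.asarray(pairs["G"], dtype=float)
    d = np.asarray(pairs["distance_m"], dtype=float)
    if not (np.isfinite(g).all() and np.isfinite(d).all()):
        raise ValueError("non-finite conductance or distance")
    if model.standardize:
        for name, v in (("G", g), ("distance_m", d)):
            if v.std() == 0:
                raise ValueError(f"zero-variance predictor {name} "
                                 "cannot be standardized")
        g = (g - g.mean()) / g.std()
        d = (d - d.mean()) / d.std()
    eta = model.beta0 + model.beta_G * g + model.beta_d * d
    rng = np.random.default_rng(seed + _OFF_TRANSIT)
    out = pairs.copy()
    out["transited"] = (rng.random(len(out)) < expit(eta)).astype(int)
    return out
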