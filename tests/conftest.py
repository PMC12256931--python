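import numpy as np
import pytest

import waveways as w
from waveways.synthetic import generate_land_mask


@pytest.fixture(scope="session")
def landscape_cfg():
    return w.LandscapeConfig(extent_m=(9000.0, 9000.0), cell_size_m=150.0,
                             seed=7, land_fraction=0.6, n_streams=5,
                             ruggedness_scale=800.0)


@pytest.fixture(scope="session")
def elevation(landscape_cfg):
    return w.generate_elevation(landscape_cfg)


@pytest.fixture(scope="session")
def land(elevation, landscape_cfg):
    return generate_land_mask(elevation, landscape_cfg)


@pytest.fixture(scope="session")
def cumulative(elevation, land, landscape_cfg):
    """Full cumulative 1-10 resistance surface for the session landscape."""
    from waveways import resistance as rs
    cover, age = w.generate_landcover(elevation, landscape_cfg)
    tri = rs.terrain_ruggedness_index(elevation)
    t_layer = rs.classify_continuous(tri, rs.TRI_SCHEME)
    l_layer = rs.classify_landcover(cover.like(cover.data.astype(int)), age)
    water = land.like(~(land.data > 0.5))
    dist = rs.distance_to_shore(water)
    w_layer = rs.classify_water(dist, water)
    return rs.combine_layers(t_layer, l_layer, w_layer)


def random_resistor_graph(rng, n_max=200):
    """Random connected resistor network for solver oracles.

    A spanning-tree backbone guarantees connectivity; extra random edges are
    added on top. Returns a ResistanceGraph with no raster attached.
    """
    from waveways.circuit import ResistanceGraph

    n = int(rng.integers(5, n_max + 1))
    edges = {(int(rng.integers(0, k)), k) for k in range(1, n)}
    n_extra = int(rng.integers(0, 2 * n))
    for _ in range(n_extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    edges = np.array(sorted(edges))
    res = rng.uniform(0.5, 10.0, size=len(edges))
    cells = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    return ResistanceGraph(cells, edges, res)


def dense_effective_resistance(graph, s, t):
    """Oracle: R̂ = L⁺_ss + L⁺_tt − 2 L⁺_st from the dense pseudo-inverse.

    The cutoff discards only the null mode of the connected Laplacian
    (numpy's default relative cutoff can misjudge it).
    """
    L = graph.laplacian().toarray()
    Lp = np.linalg.pinv(L, hermitian=True, rcond=1e-10)
    return Lp[s, s] + Lp[t, t] - 2 * Lp[s, t]
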