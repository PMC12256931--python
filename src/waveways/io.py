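"""Plain-text I/O: GeoJSON for vectors, CSV for tables, ASCII for rasters.

Raster I/O lives in :mod:`waveways.grid`; this module round-trips the vector
and tabular artifacts (streams, reaches, sites, detections, transits,
conductance matrices) through text formats.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .nodes import FocalNodeSet

__all__ = ["write_geojson", "read_geojson", "write_nodes_csv",
           "read_nodes_csv", "write_matrix_csv", "read_matrix_csv"]


def write_geojson(df: pd.DataFrame, path, geometry_col: str = "geometry"
                  ) -> None:
    """Write a DataFrame with a shapely geometry column as GeoJSON."""
    features = []
    for _, row in df.iterrows():
        props = {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in row.items() if k != geometry_col}
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(row[geometry_col])})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = shape(feat["geometry"])
        rows.append(rec)
    return pd.DataFrame(rows)


def write_nodes_csv(nodes: FocalNodeSet, path) -> None:
    nodes.table.to_csv(path, index=False)


def read_nodes_csv(path) -> FocalNodeSet:
    return FocalNodeSet(pd.read_csv(path))


def write_matrix_csv(matrix: np.ndarray, node_ids, path) -> None:
    """Symmetric pairwise matrix (R̂ or Ĝ) as a labelled CSV."""
    pd.DataFrame(matrix, index=node_ids, columns=node_ids).to_csv(path)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
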