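"""Random city maps and map file I/O.

Every simulation runs on a map of ``L`` cities placed uniformly at random on
the unit square.  Because the kernel's normalisation constant absorbs any
global distance scale, only the *shape* of the point pattern matters, so the
unit square is as good as any domain.  A minimum pairwise separation
``d_min`` (rejection sampling) keeps the ``d^-alpha`` factor from diverging
when two cities happen to land on top of each other.

Maps round-trip through a small CSV with header ``city_id,x,y,K``
(0-based contiguous ids).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.spatial.distance import pdist, squareform

from .model_core import CityMap, DegenerateMapError, ParameterError

__all__ = [
    "MapGenerationError",
    "generate_map",
    "distance_matrix",
    "write_map_csv",
    "read_map_csv",
]

MAP_CSV_HEADER = ["city_id", "x", "y", "K"]

#: full resampling attempts before giving up on an infeasible (L, d_min)
MAX_ATTEMPTS = 1000


class MapGenerationError(RuntimeError):
    """Could not place L cities at the requested minimum separation."""


def distance_matrix(coords: ArrayLike) -> NDArray[np.float64]:
    """Pairwise Euclidean distances between planar points.

    Symmetric with a zero diagonal; raises on duplicate points, which
    would make the inverse-distance kernel singular.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ParameterError("need at least 2 planar points")
    dist = squareform(pdist(coords))
    off = dist[~np.eye(len(dist), dtype=bool)]
    if np.any(off == 0):
        raise DegenerateMapError("duplicate points in coordinate set")
    return dist


def generate_map(
    L: int = 10,
    K_value: float = 5000.0,
    seed: int | None = None,
    d_min: float = 0.05,
) -> CityMap:
    """Draw ``L`` cities uniformly on the unit square, all with size ``K_value``.

    The whole configuration is resampled until every pairwise distance is at
    least ``d_min`` (at most ``MAX_ATTEMPTS`` tries).  Reproducible under
    ``seed``.
    """
    if L < 2:
        raise ParameterError("need at least 2 cities")
    if K_value <= 0:
        raise ParameterError("K_value must be > 0")
    if d_min < 0:
        raise ParameterError("d_min must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        coords = rng.random((L, 2))
        dist = squareform(pdist(coords))
        off = dist[~np.eye(L, dtype=bool)]
        if off.min() >= d_min and off.min() > 0:
            K = np.full(L, float(K_value))
            return CityMap(coords=coords, dist=dist, K=K)
    raise MapGenerationError(
        f"could not place {L} cities with min separation {d_min} "
        f"in {MAX_ATTEMPTS} attempts"
    )


def write_map_csv(cmap: CityMap, path: str | Path) -> None:
    """Write a map as CSV ``city_id,x,y,K``, one row per city, ids from 0."""
    df = pd.DataFrame(
        {
            "city_id": np.arange(cmap.L),
            "x": cmap.coords[:, 0],
            "y": cmap.coords[:, 1],
            "K": cmap.K,
        }
    )
    df.to_csv(path, index=False)


def read_map_csv(path: str | Path) -> CityMap:
    """Read a map written by :func:`write_map_csv`; recomputes distances."""
    df = pd.read_csv(path)
    if list(df.columns) != MAP_CSV_HEADER:
        raise ParameterError(
            f"map CSV must have header {','.join(MAP_CSV_HEADER)}, got {list(df.columns)}"
        )
    ids = df["city_id"].to_numpy()
    if not np.array_equal(ids, np.arange(len(df))):
        raise ParameterError("city_id must be contiguous from 0")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    return CityMap(
        coords=coords,
        dist=distance_matrix(coords),
        K=df["K"].to_numpy(dtype=float),
    )
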