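"""Outcome measures: inverse Simpson diversity, survival, boxplot summaries.

A city's diversity at the end of a run is the inverse Simpson index of its
origin composition, ``S_j = 1 / sum_x p_x^2`` with ``p_x`` the fraction of
city ``j``'s residents whose origin is ``x``.  ``S_j = 1`` means everyone
shares one origin; ``S_j = L`` means all ``L`` origins are equally
represented; an empty city is assigned ``S_j = 0`` by convention.

A city *survives* a run if its final total population strictly exceeds the
extinction threshold ``epsilon`` (default 1 person — deterministic flows
never reach exactly zero, so "fewer than one whole person" is the natural
operational reading of extinction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .model_core import ParameterError, PopulationState

__all__ = [
    "CityDiversity",
    "simpson_index",
    "surviving_cities",
    "city_diversity",
    "boxplot_stats",
    "write_metrics_csv",
]


@dataclass(frozen=True)
class CityDiversity:
    """Per-city diversity and survival for one final state."""

    S: NDArray[np.float64]
    surviving: NDArray[np.bool_]
    count_surviving: int

    def surviving_S(self) -> NDArray[np.float64]:
        """Diversity indices of the surviving cities only."""
        return self.S[self.surviving]


def simpson_index(composition: ArrayLike) -> float:
    """Inverse Simpson index of one city's origin composition.

    ``1 / sum_x (n_x / n_total)^2``; 0 for an empty city.  Invariant to
    rescaling all counts, maximal (= number of origins) at the uniform
    composition.
    """
    counts = np.asarray(composition, dtype=float)
    if np.any(counts < 0):
        raise ParameterError("composition counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 / np.sum(p**2))


def surviving_cities(
    state: PopulationState, epsilon: float = 1.0
) -> tuple[NDArray[np.bool_], int]:
    """Mask and count of cities with total population strictly above ``epsilon``."""
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    totals = state.city_totals()
    mask = totals > epsilon
    return mask, int(mask.sum())


def city_diversity(state: PopulationState, epsilon: float = 1.0) -> CityDiversity:
    """Inverse Simpson index of every city plus the survival mask."""
    S = np.array([simpson_index(row) for row in state.n])
    mask, count = surviving_cities(state, epsilon)
    return CityDiversity(S=S, surviving=mask, count_surviving=count)


def boxplot_stats(values: ArrayLike) -> dict:
    """Median, quartiles, 1.5 IQR whiskers, and outliers of a sample.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data points within 1.5 IQR of the quartiles,
    anything beyond is flagged as an outlier.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ParameterError("boxplot_stats needs a non-empty sample")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": np.sort(x[(x < lo_fence) | (x > hi_fence)]).tolist(),
    }


def write_metrics_csv(
    state: PopulationState, path: str | Path, epsilon: float = 1.0
) -> pd.DataFrame:
    """Per-city metrics CSV ``city_id,total_population,S,surviving``."""
    div = city_diversity(state, epsilon)
    df = pd.DataFrame(
        {
            "city_id": np.arange(state.L),
            "total_population": state.city_totals(),
            "S": div.S,
            "surviving": div.surviving.astype(int),
        }
    )
    df.to_csv(path, index=False)
    return df
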