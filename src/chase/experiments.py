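"""Ensemble experiments over random maps.

Three experiment structures are provided, mirroring the model's headline
analyses:

* :func:`legacy_effect` — one map, several mindset timescales ``tau_beta``;
  shows that transient priorities can change the long-term state.
* :func:`k_sweep` — mean number of surviving cities as a function of the
  characteristic size ``K``, averaged over fresh random maps.
* :func:`gamma_diversity` — distribution of surviving-city diversity as a
  function of the social-tie strength ``gamma``, grouped by how many cities
  survived (survival count strongly conditions diversity: with a single
  survivor everyone is in it and S equals L by construction).

Every run's seed is derived deterministically from
``(master_seed, cell index, replicate index)``, so any single run can be
replayed in isolation and ensemble statistics do not depend on execution
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .dynamics import SimulationResult, run
from .mapgen import generate_map
from .metrics import boxplot_stats, city_diversity
from .model_core import CityMap, ModelParameters, ParameterError

__all__ = [
    "EnsembleSummary",
    "LegacyResult",
    "derive_seed",
    "legacy_effect",
    "k_sweep",
    "gamma_diversity",
    "write_summary_json",
    "write_summary_csv",
]

ENSEMBLE_CSV_HEADER = [
    "K",
    "gamma",
    "tau_beta",
    "n_surviving",
    "mean_surviving",
    "S_median",
    "S_q25",
    "S_q75",
    "n_runs",
]


def derive_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-run seed from (master seed, cell, replicate).

    Uses a seed sequence so nearby indices decorrelate; the result is kept
    below 2**31 so it is portable as a plain int seed.
    """
    ss = np.random.SeedSequence([int(master_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class EnsembleSummary:
    """Aggregated results of a sweep over random maps.

    ``cells`` maps a parameter cell key to a dict with the cell's parameter
    values, realization count, per-run seeds, mean surviving count, and the
    pooled surviving-city diversity sample with its boxplot statistics.
    """

    kind: str
    master_seed: int
    L: int
    params_base: ModelParameters
    cells: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "kind": self.kind,
            "master_seed": self.master_seed,
            "L": self.L,
            "params_base": asdict(self.params_base),
            "cells": self.cells,
        }


@dataclass
class LegacyResult:
    """Per-``tau_beta`` runs on one shared map plus final-state distances."""

    tau_values: list[float]
    results: dict[float, SimulationResult]
    final_populations: dict[float, NDArray[np.float64]]
    #: distance[a][b] = max over cities of |final total pop (tau_a) - (tau_b)|
    distance: NDArray[np.float64]

    def differs(self, tau_a: float, tau_b: float, threshold: float = 10.0) -> bool:
        """Whether two mindset timescales reached materially different states.

        The comparison is the max absolute per-city total-population
        difference; ``threshold`` (persons) makes the qualitative notion of
        "different final state" operational.
        """
        ia, ib = self.tau_values.index(tau_a), self.tau_values.index(tau_b)
        return bool(self.distance[ia, ib] > threshold)


def legacy_effect(
    cmap: CityMap,
    tau_values: Sequence[float],
    params_base: ModelParameters | None = None,
    record: int | str = "final",
) -> LegacyResult:
    """Run the model once per mindset timescale on one fixed map.

    Keeping the map fixed isolates the effect of the transient: any
    difference between final states is attributable to how fast people's
    priorities shifted, not to geography.
    """
    params_base = params_base or ModelParameters()
    tau_values = [float(t) for t in tau_values]
    results: dict[float, SimulationResult] = {}
    finals: dict[float, NDArray[np.float64]] = {}
    for tau in tau_values:
        res = run(cmap, params_base.with_(tau_beta=tau), record=record)
        results[tau] = res
        finals[tau] = res.final_state.city_totals()
    m = len(tau_values)
    distance = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            distance[a, b] = np.max(np.abs(finals[tau_values[a]] - finals[tau_values[b]]))
    return LegacyResult(
        tau_values=tau_values,
        results=results,
        final_populations=finals,
        distance=distance,
    )


def _run_cell(
    K: float,
    params: ModelParameters,
    L: int,
    n_runs: int,
    master_seed: int,
    cell_index: int,
) -> dict:
    """Run ``n_runs`` fresh-map simulations for one parameter cell."""
    seeds, counts, pooled_S = [], [], []
    for rep in range(n_runs):
        seed = derive_seed(master_seed, cell_index, rep)
        cmap = generate_map(L=L, K_value=K, seed=seed)
        res = run(cmap, params, record="final")
        div = city_diversity(res.final_state, params.epsilon)
        seeds.append(seed)
        counts.append(div.count_surviving)
        pooled_S.extend(float(s) for s in div.surviving_S())
    return {
        "seeds": seeds,
        "surviving_counts": counts,
        "mean_surviving": float(np.mean(counts)),
        "surviving_S": pooled_S,
        "n_runs": n_runs,
    }


def k_sweep(
    K_values: Sequence[float],
    gamma: float,
    tau_beta: float,
    n_maps: int = 100,
    master_seed: int = 0,
    L: int = 10,
    params_base: ModelParameters | None = None,
) -> EnsembleSummary:
    """Mean surviving-city count per characteristic size ``K``.

    For each ``K``, ``n_maps`` simulations run on fresh seeded random maps
    and the end-of-run surviving-city counts are averaged.
    """
    if n_maps < 1:
        raise ParameterError("n_maps must be >= 1")
    params_base = params_base or ModelParameters()
    params = params_base.with_(gamma=float(gamma), tau_beta=float(tau_beta))
    summary = EnsembleSummary(
        kind="k_sweep", master_seed=master_seed, L=L, params_base=params
    )
    for ci, K in enumerate(K_values):
        cell = _run_cell(float(K), params, L, n_maps, master_seed, ci)
        cell.update(K=float(K), gamma=float(gamma), tau_beta=float(tau_beta))
        if cell["surviving_S"]:
            cell["S_stats"] = boxplot_stats(cell["surviving_S"])
        summary.cells[f"K={K}"] = cell
    return summary


def gamma_diversity(
    K_values: Sequence[float],
    gamma_values: Sequence[float],
    tau_beta: float,
    n_realizations: int = 100,
    master_seed: int = 0,
    L: int = 10,
    params_base: ModelParameters | None = None,
) -> EnsembleSummary:
    """Surviving-city diversity pooled by (gamma, surviving-city count).

    For each ``gamma``, ``n_realizations`` runs are performed per ``K`` in
    ``K_values`` (fresh random map each); the inverse Simpson indices of all
    surviving cities are pooled across runs and ``K`` into cells keyed by
    the run's surviving-city count, and each non-empty cell gets boxplot
    statistics.  Empty cells are simply absent.
    """
    if n_realizations < 1:
        raise ParameterError("n_realizations must be >= 1")
    params_base = params_base or ModelParameters()
    summary = EnsembleSummary(
        kind="gamma_diversity",
        master_seed=master_seed,
        L=L,
        params_base=params_base.with_(tau_beta=float(tau_beta)),
    )
    for gi, gamma in enumerate(gamma_values):
        params = params_base.with_(gamma=float(gamma), tau_beta=float(tau_beta))
        groups: dict[int, list[float]] = {}
        group_runs: dict[int, int] = {}
        seeds = []
        n_runs = 0
        for ki, K in enumerate(K_values):
            cell_index = gi * len(K_values) + ki
            for rep in range(n_realizations):
                seed = derive_seed(master_seed, cell_index, rep)
                cmap = generate_map(L=L, K_value=float(K), seed=seed)
                res = run(cmap, params, record="final")
                div = city_diversity(res.final_state, params.epsilon)
                groups.setdefault(div.count_surviving, []).extend(
                    float(s) for s in div.surviving_S()
                )
                group_runs[div.count_surviving] = group_runs.get(div.count_surviving, 0) + 1
                seeds.append(seed)
                n_runs += 1
        summary.cells[f"gamma={gamma}"] = {
            "gamma": float(gamma),
            "tau_beta": float(tau_beta),
            "K_values": [float(K) for K in K_values],
            "seeds": seeds,
            "n_runs": n_runs,
            "groups": {
                str(ns): {
                    "surviving_S": S,
                    "n_cities": len(S),
                    "n_runs_group": group_runs[ns],
                    "S_stats": boxplot_stats(S) if S else None,
                }
                for ns, S in sorted(groups.items())
            },
        }
    return summary


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_summary_json(summary: EnsembleSummary, path: str | Path) -> None:
    """Full nested summary, including every per-run seed, as JSON."""
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1)


def write_summary_csv(summary: EnsembleSummary, path: str | Path) -> pd.DataFrame:
    """Flat per-cell table: ``K,gamma,tau_beta,n_surviving,mean_surviving,
    S_median,S_q25,S_q75,n_runs``.

    For a K sweep ``n_surviving`` is empty (cells are per-K); for a
    gamma-diversity summary one row is emitted per (gamma, surviving-count)
    group and ``K`` is empty (pooled across K values).
    """
    rows = []
    for cell in summary.cells.values():
        if summary.kind == "k_sweep":
            st = cell.get("S_stats", {})
            rows.append(
                {
                    "K": cell["K"],
                    "gamma": cell["gamma"],
                    "tau_beta": cell["tau_beta"],
                    "n_surviving": "",
                    "mean_surviving": cell["mean_surviving"],
                    "S_median": st.get("median", ""),
                    "S_q25": st.get("q25", ""),
                    "S_q75": st.get("q75", ""),
                    "n_runs": cell["n_runs"],
                }
            )
        else:
            for ns, grp in cell["groups"].items():
                st = grp["S_stats"] or {"median": "", "q25": "", "q75": ""}
                rows.append(
                    {
                        "K": "",
                        "gamma": cell["gamma"],
                        "tau_beta": cell["tau_beta"],
                        "n_surviving": int(ns),
                        "mean_surviving": "",
                        "S_median": st["median"],
                        "S_q25": st["q25"],
                        "S_q75": st["q75"],
                        "n_runs": grp["n_cities"],
                    }
                )
    df = pd.DataFrame(rows, columns=ENSEMBLE_CSV_HEADER)
    df.to_csv(path, index=False)
    return df
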