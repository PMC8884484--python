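"""Run configuration and structured output writers.

Configs are flat JSON key-value files mirroring :class:`ModelParameters`
plus the map source and output options.  Command-line flags override file
values; unknown keys are rejected rather than silently ignored, and every
run writes its fully resolved config (defaults applied, seeds recorded)
next to its outputs so it can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SimulationResult
from .metrics import city_diversity
from .model_core import ModelParameters, ParameterError

__all__ = ["RunConfig", "load_config", "write_trajectory", "read_trajectory"]

TRAJECTORY_CSV_HEADER = ["t", "city_id", "origin_id", "population"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_CONFIG_ONLY_FIELDS = {"L", "K", "map_file", "map_seed", "d_min", "out_dir", "thin"}
_KNOWN_KEYS = _PARAM_FIELDS | _CONFIG_ONLY_FIELDS


@dataclass
class RunConfig:
    """A fully resolved simulation configuration.

    ``map_file`` (a ``city_id,x,y,K`` CSV) takes precedence over random
    generation with ``(L, K, map_seed, d_min)``.
    """

    params: ModelParameters = field(default_factory=ModelParameters)
    L: int = 10
    K: float = 5000.0
    map_file: str | None = None
    map_seed: int = 0
    d_min: float = 0.05
    out_dir: str = "chase_out"
    thin: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.update(
            L=self.L,
            K=self.K,
            map_file=self.map_file,
            map_seed=self.map_seed,
            d_min=self.d_min,
            out_dir=self.out_dir,
            thin=self.thin,
        )
        return d

    def make_map(self):
        from .mapgen import generate_map, read_map_csv

        if self.map_file:
            return read_map_csv(self.map_file)
        return generate_map(L=self.L, K_value=self.K, seed=self.map_seed, d_min=self.d_min)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional JSON file plus overrides.

    Defaults follow the benchmark setup (delta 0.2, alpha 1, 3,000 natives
    in each of 10 cities, 5,000 steps, extinction threshold 1 person,
    deterministic updating).  ``overrides`` (typically CLI flags) win over
    file values.  Unknown keys and out-of-range values raise with the
    offending key named.
    """
    merged: dict = {}
    if path is not None:
        with open(path) as fh:
            try:
                file_values = json.load(fh)
            except json.JSONDecodeError as e:
                raise ParameterError(f"config {path} is not valid JSON: {e}") from e
        if not isinstance(file_values, dict):
            raise ParameterError("config must be a JSON object of key-value pairs")
        merged.update(file_values)
    for key, value in (overrides or {}).items():
        if value is not None:
            merged[key] = value
    unknown = set(merged) - _KNOWN_KEYS
    if unknown:
        raise ParameterError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    param_kwargs = {k: v for k, v in merged.items() if k in _PARAM_FIELDS}
    try:
        params = ModelParameters(**param_kwargs)
    except ParameterError:
        raise
    cfg_kwargs = {k: v for k, v in merged.items() if k in _CONFIG_ONLY_FIELDS}
    cfg = RunConfig(params=params, **cfg_kwargs)
    if cfg.L < 2:
        raise ParameterError(f"L must be >= 2, got {cfg.L}")
    if cfg.K <= 0:
        raise ParameterError(f"K must be > 0, got {cfg.K}")
    if cfg.thin < 1:
        raise ParameterError(f"thin must be >= 1, got {cfg.thin}")
    return cfg


def write_trajectory(result: SimulationResult, out_dir: str | Path) -> Path:
    """Write a run to ``out_dir``: long-format CSV plus a JSON sidecar.

    ``trajectory.csv`` has columns ``t,city_id,origin_id,population`` (one
    row per recorded state and matrix cell); ``run.json`` records the
    parameters, the map, the mindset series, and final-state metrics.
    Returns the output directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = result.map.L
    frames = []
    city_idx, origin_idx = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    for state in result.trajectory:
        frames.append(
            pd.DataFrame(
                {
                    "t": state.t,
                    "city_id": city_idx.ravel(),
                    "origin_id": origin_idx.ravel(),
                    "population": state.n.ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out / "trajectory.csv", index=False, float_format="%.10g")

    final = result.final_state
    div = city_diversity(final, result.params.epsilon)
    sidecar = {
        "params": dataclasses.asdict(result.params),
        "map": {
            "coords": result.map.coords.tolist(),
            "K": result.map.K.tolist(),
        },
        "beta_series": result.beta_series.tolist(),
        "recorded_steps": [s.t for s in result.trajectory],
        "final": {
            "total_population": final.total(),
            "city_totals": final.city_totals().tolist(),
            "S": div.S.tolist(),
            "surviving": div.surviving.astype(int).tolist(),
            "count_surviving": div.count_surviving,
        },
    }
    with open(out / "run.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out


def read_trajectory(out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back a run written by :func:`write_trajectory`."""
    out = Path(out_dir)
    df = pd.read_csv(out / "trajectory.csv")
    if list(df.columns) != TRAJECTORY_CSV_HEADER:
        raise ParameterError(
            f"trajectory CSV must have header {','.join(TRAJECTORY_CSV_HEADER)}"
        )
    with open(out / "run.json") as fh:
        sidecar = json.load(fh)
    return df, sidecar
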