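"""Time evolution of the population state under the migration kernels.

Two update modes are provided.  The default, *deterministic expected flow*,
propagates real-valued populations through the kernels
(``n'[i, k] = sum_j w_k[i, j] n[j, k]``), which yields smooth,
bit-reproducible trajectories.  The *stochastic* mode instead allocates the
integer individuals of every (city, origin) cell with a multinomial draw
from that cell's column of probabilities; totals are then conserved exactly
as integer counts and runs are reproducible under a seed.

Updates are synchronous: all L origin kernels for step ``t`` are computed
from the state at ``t`` before anyone moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from .model_core import (
    CityMap,
    ModelParameters,
    ParameterError,
    PopulationState,
    TransitionKernel,
    _inverse_distance,
    _kernel_parts,
    beta_schedule,
    build_kernels,
)

log = logging.getLogger("chase.dynamics")

__all__ = [
    "SimulationResult",
    "initial_state",
    "step_deterministic",
    "step_stochastic",
    "run",
]


@dataclass
class SimulationResult:
    """A completed simulation: recorded states, mindset series, inputs.

    ``trajectory`` holds the recorded states in time order; with the default
    recording every step it has length ``T + 1`` and ``trajectory[0]`` is
    the initial state.  ``beta_series`` is ``beta_t`` for t = 0 ... T.
    """

    trajectory: list[PopulationState]
    beta_series: NDArray[np.float64]
    map: CityMap
    params: ModelParameters

    @property
    def final_state(self) -> PopulationState:
        return self.trajectory[-1]

    def total_population(self) -> float:
        return self.final_state.total()


def initial_state(L: int, n0: float) -> PopulationState:
    """Everyone starts at home: ``n[j, x] = n0`` if ``j == x`` else 0."""
    if L < 2:
        raise ParameterError("need at least 2 cities")
    if n0 <= 0:
        raise ParameterError("n0 must be > 0")
    return PopulationState(n=np.eye(L) * float(n0), t=0)


def _as_kernel_array(
    kernels: Sequence[TransitionKernel] | NDArray[np.float64], L: int
) -> NDArray[np.float64]:
    if isinstance(kernels, np.ndarray):
        W = kernels
    else:
        W = np.stack([k.w if isinstance(k, TransitionKernel) else np.asarray(k) for k in kernels])
    if W.shape != (L, L, L):
        raise ParameterError(f"need one L x L kernel per origin, got shape {W.shape}")
    return W


def step_deterministic(
    state: PopulationState,
    kernels: Sequence[TransitionKernel] | NDArray[np.float64],
) -> PopulationState:
    """Expected-flow update: ``n'[i, k] = sum_j w_k[i, j] n[j, k]``.

    Column-stochastic kernels make this conserve each origin group's total
    exactly (up to float roundoff).
    """
    W = _as_kernel_array(kernels, state.L)
    n_new = np.einsum("kij,jk->ik", W, state.n)
    return PopulationState(n=n_new, t=state.t + 1)


def step_stochastic(
    state: PopulationState,
    kernels: Sequence[TransitionKernel] | NDArray[np.float64],
    rng: np.random.Generator,
) -> PopulationState:
    """Multinomial update: each (city, origin) cell's individuals are dealt
    to destinations by one multinomial draw from that cell's column.
    """
    if not np.all(state.n == np.round(state.n)):
        raise ParameterError("stochastic mode requires integer populations")
    W = _as_kernel_array(kernels, state.L)
    L = state.L
    n_new = np.zeros((L, L))
    for k in range(L):
        for j in range(L):
            count = int(state.n[j, k])
            if count == 0:
                continue
            n_new[:, k] += rng.multinomial(count, W[k, :, j])
    return PopulationState(n=n_new, t=state.t + 1)


def _step_flow_fast(
    n: NDArray[np.float64],
    beta: float,
    cmap: CityMap,
    params: ModelParameters,
    Dinv: NDArray[np.float64],
) -> NDArray[np.float64]:
    """One expected-flow step without materialising the (L, L, L) kernels.

    Algebraically identical to ``step_deterministic(build_kernels(...))``:
    the inflow to city ``i`` factorises as ``A[i, k] * sum_j Dinv[i, j] *
    (1 - s_j) n[j, k] / Z[j, k]``, one matrix product per step.
    """
    s, A, Dinv, Z = _kernel_parts(n, beta, cmap, params, Dinv)
    degenerate = Z <= 0.0
    Zsafe = np.where(degenerate, 1.0, Z)
    outflow = (1.0 - s)[:, None] * n / Zsafe
    outflow[degenerate] = 0.0
    # degenerate (j, k) columns keep their would-be emigrants at home
    stay = np.where(degenerate, n, s[:, None] * n)
    return stay + A * (Dinv @ outflow)


def run(
    cmap: CityMap,
    params: ModelParameters,
    record: int | str = 1,
) -> SimulationResult:
    """Simulate ``params.T`` steps from the all-natives initial state.

    Parameters
    ----------
    cmap
        The city map (coordinates, distances, characteristic sizes).
    params
        Model parameters; ``params.mode`` selects expected-flow or
        multinomial updating.
    record
        Trajectory thinning: ``1`` records every state (default), an
        integer ``m`` records every m-th state plus the final one,
        ``"final"`` records only the initial and final states.

    Deterministic runs are bit-reproducible; stochastic runs are
    reproducible given ``params.seed``.
    """
    if cmap.L < 2:
        raise ParameterError("need at least 2 cities")
    thin = 0 if record == "final" else int(record)
    if record != "final" and thin < 1:
        raise ParameterError("record must be 'final' or a positive integer")
    state = initial_state(cmap.L, params.n0)
    beta_series = np.asarray(beta_schedule(np.arange(params.T + 1), params.tau_beta), dtype=float)
    if beta_series.ndim == 0:
        beta_series = beta_series[None]
    trajectory = [state]
    Dinv = _inverse_distance(cmap, params.alpha)
    rng = np.random.default_rng(params.seed) if params.mode == "stochastic" else None
    n = state.n
    for t in range(params.T):
        if params.mode == "deterministic":
            n = _step_flow_fast(n, float(beta_series[t]), cmap, params, Dinv)
            new_state = PopulationState(n=n, t=t + 1)
        else:
            cur = PopulationState(n=n, t=t)
            W = build_kernels(cur, t, cmap, params, Dinv)
            new_state = step_stochastic(cur, W, rng)
            n = new_state.n
        if thin and (t + 1) % thin == 0:
            trajectory.append(new_state)
        if (t + 1) % 1000 == 0:
            log.debug("step %d/%d, beta=%.4f", t + 1, params.T, beta_series[t])
    if trajectory[-1].t != params.T:
        trajectory.append(PopulationState(n=n, t=params.T))
    return SimulationResult(
        trajectory=trajectory, beta_series=beta_series, map=cmap, params=params
    )
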