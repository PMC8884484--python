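"""Domain types and the per-origin transition kernel of the migration model.

The model is a discrete-time Markov chain on ``L`` cities scattered on a
plane.  People are labelled by their city of origin; the probability that an
individual of origin ``k`` currently in city ``j`` moves to city ``i`` during
step ``t`` combines four drivers:

* **agglomeration** — a destination-population factor raised to an exponent
  ``beta_t`` in [0, 1];
* **changing mindset** — ``beta_t = 1 - exp(-t / tau_beta)`` grows from 0
  (distance-only decisions) toward 1 (full weighting of opportunities and
  ties) on a timescale ``tau_beta``;
* **social ties** — people of the mover's own origin at a candidate
  destination are weighted by ``gamma`` (neutral at 1);
* **environment** — Ricker-style pressure ``exp(-n / K)`` penalising cities
  whose total population exceeds their characteristic size ``K``.

Each origin has its own column-stochastic ``L x L`` kernel per step:
``w[i, j]`` is P(j -> i) and every column sums to one, so people are
conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ParameterError",
    "DegenerateMapError",
    "NumericalError",
    "CityMap",
    "ModelParameters",
    "PopulationState",
    "TransitionKernel",
    "beta_schedule",
    "staying_probability",
    "attraction_weight",
    "transition_kernel",
    "build_kernels",
]

#: columns of a kernel must sum to one within this tolerance
COLUMN_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DegenerateMapError(ValueError):
    """The city map is unusable (coincident cities, zero distances...)."""


class NumericalError(ArithmeticError):
    """A non-finite value appeared while assembling a kernel."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CityMap:
    """A set of cities: planar coordinates, distances, characteristic sizes.

    Parameters
    ----------
    coords
        ``(L, 2)`` array of city positions in dimensionless map units.
    dist
        ``(L, L)`` symmetric Euclidean distance matrix; zero diagonal.
    K
        Length-``L`` vector of characteristic population sizes (persons):
        the total population that maximises a city's attractiveness when
        the agglomeration exponent equals 1.
    """

    coords: NDArray[np.float64]
    dist: NDArray[np.float64]
    K: NDArray[np.float64]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        dist = np.asarray(self.dist, dtype=float)
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "dist", dist)
        object.__setattr__(self, "K", K)
        L = coords.shape[0]
        if L < 2 or coords.ndim != 2 or coords.shape[1] != 2:
            raise ParameterError("coords must be an (L, 2) array with L >= 2")
        if dist.shape != (L, L):
            raise ParameterError("dist must be L x L")
        if K.shape != (L,):
            raise ParameterError("K must have length L")
        if np.any(K <= 0):
            raise ParameterError("every K_j must be > 0")
        if not np.allclose(dist, dist.T, atol=1e-12):
            raise DegenerateMapError("distance matrix is not symmetric")
        if np.any(np.diag(dist) != 0.0):
            raise DegenerateMapError("distance matrix diagonal must be zero")
        off = dist[~np.eye(L, dtype=bool)]
        if np.any(off <= 0):
            raise DegenerateMapError("coincident cities: zero off-diagonal distance")
        recomputed = np.hypot(
            coords[:, 0][:, None] - coords[:, 0][None, :],
            coords[:, 1][:, None] - coords[:, 1][None, :],
        )
        if not np.allclose(dist, recomputed, rtol=1e-9, atol=1e-12):
            raise DegenerateMapError("dist does not match Euclidean distances of coords")

    @property
    def L(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_coords(cls, coords: ArrayLike, K: ArrayLike) -> "CityMap":
        """Build a map from coordinates, computing the distance matrix."""
        from .mapgen import distance_matrix  # local import: avoid cycle

        coords = np.asarray(coords, dtype=float)
        K = np.broadcast_to(np.asarray(K, dtype=float), (coords.shape[0],)).copy()
        return cls(coords=coords, dist=distance_matrix(coords), K=K)


UpdateMode = Literal["deterministic", "stochastic"]


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of one simulation.

    Defaults are the benchmark configuration used throughout the model's
    headline experiments: ``delta=0.2``, ``alpha=1``, ``gamma=50``,
    ``tau_beta=120``, 5,000 steps, 3,000 natives per city.

    Attributes
    ----------
    delta
        Maximum fraction of a city's population emigrating in one step,
        in (0, 1].
    alpha
        Distance-deterrence exponent (d^-alpha); 1 as in classic gravity
        models.
    gamma
        Social-tie weight on same-origin people at a destination; 1 is
        neutral (the numerator then reduces to total destination
        population).
    tau_beta
        Mindset timescale in steps; 0 means beta_t = 1 for all t.
    T
        Number of steps to simulate.
    n0
        Initial natives per city (persons).
    epsilon
        End-of-run extinction threshold (persons): a city survives iff
        its final total population strictly exceeds epsilon.
    mode
        "deterministic" expected-flow propagation of real-valued
        populations, or "stochastic" multinomial sampling of integer
        individuals.
    seed
        Seed for the stochastic mode's random source.
    """

    delta: float = 0.2
    alpha: float = 1.0
    gamma: float = 50.0
    tau_beta: float = 120.0
    T: int = 5000
    n0: float = 3000.0
    epsilon: float = 1.0
    mode: UpdateMode = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise ParameterError(f"delta must be in (0, 1], got {self.delta}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.gamma < 0:
            raise ParameterError(f"gamma must be >= 0, got {self.gamma}")
        if self.tau_beta < 0:
            raise ParameterError(f"tau_beta must be >= 0, got {self.tau_beta}")
        if int(self.T) != self.T or self.T < 0:
            raise ParameterError(f"T must be a non-negative integer, got {self.T}")
        if self.n0 <= 0:
            raise ParameterError(f"n0 must be > 0, got {self.n0}")
        if self.epsilon < 0:
            raise ParameterError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ParameterError(f"mode must be deterministic|stochastic, got {self.mode}")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Population matrix at one time index.

    ``n[j, x]`` is the number of people of origin ``x`` currently living in
    city ``j``.  Entries are non-negative reals (deterministic mode) or
    integers (stochastic mode); per-origin column sums are conserved over
    time because there are no births or deaths.
    """

    n: NDArray[np.float64]
    t: int = 0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 2 or self.n.shape[0] != self.n.shape[1]:
            raise ParameterError("population matrix must be square (L x L)")
        if np.any(self.n < 0):
            raise ParameterError("populations must be non-negative")
        if self.t < 0:
            raise ParameterError("time index must be >= 0")

    @property
    def L(self) -> int:
        return self.n.shape[0]

    def city_totals(self) -> NDArray[np.float64]:
        """Total population per city (summed over origins)."""
        return self.n.sum(axis=1)

    def origin_totals(self) -> NDArray[np.float64]:
        """Total population per origin group (summed over cities)."""
        return self.n.sum(axis=0)

    def total(self) -> float:
        return float(self.n.sum())


@dataclass(frozen=True)
class TransitionKernel:
    """Column-stochastic movement probabilities for one origin and one step.

    ``w[i, j]`` is the probability that an origin-``k`` individual in city
    ``j`` moves to city ``i`` this step; each column sums to one.  ``C``
    holds the per-column normalisation constants of the off-diagonal
    weights (0 where a column had no admissible destination).
    """

    w: NDArray[np.float64]
    C: NDArray[np.float64]
    origin: int
    t: int
    beta: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        colsums = w.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise NumericalError(f"kernel columns must sum to 1, got {colsums}")


# ---------------------------------------------------------------------------
# kernel ingredients
# ---------------------------------------------------------------------------


def beta_schedule(t: ArrayLike, tau_beta: float) -> NDArray[np.float64] | float:
    """Mindset schedule ``beta_t = 1 - exp(-t / tau_beta)``.

    Starts at 0 when ``t = 0`` and rises to 1 with timescale ``tau_beta``.
    ``tau_beta = 0`` is defined as ``beta_t = 1`` for all ``t`` (the
    instantaneous-mindset limit).  Accepts scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("time index t must be >= 0")
    if tau_beta < 0:
        raise ParameterError("tau_beta must be >= 0")
    if tau_beta == 0:
        out = np.ones_like(t_arr)
    else:
        out = -np.expm1(-t_arr / tau_beta)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _stay_bonus(n_total: ArrayLike, K: ArrayLike, beta: float) -> NDArray[np.float64]:
    """The stabilised agglomeration-environment factor in the stay branch.

    ``(e/beta)^beta (n/K)^beta exp(-n/K)``; its maximum over ``n`` is exactly
    1 (attained at ``n = beta K``), which keeps the staying probability
    within ``[1 - delta, 1]``.  At ``beta = 0`` the factor degenerates to
    ``exp(-n/K)`` with the conventions ``0^0 := 1`` and
    ``(e/beta)^beta -> 1``.
    """
    n = np.asarray(n_total, dtype=float)
    K = np.asarray(K, dtype=float)
    ratio = n / K
    if beta == 0:
        return np.exp(-ratio)
    # log-space evaluation: stable for beta -> 0+ and for empty cities
    # (ratio = 0 gives exponent -inf, hence bonus 0, i.e. 0^beta = 0)
    with np.errstate(divide="ignore"):
        exponent = beta * (1.0 + np.log(ratio) - math.log(beta)) - ratio
    return np.exp(exponent)


def staying_probability(
    n_total: float, K_j: float, beta: float, delta: float
) -> float:
    """Probability ``w_jj`` of staying in city ``j`` for one step.

    ``1 - delta + delta * (e/beta)^beta (n/K)^beta exp(-n/K)``; always in
    ``[1 - delta, 1]`` and equal to 1 exactly when ``n_total = K_j`` and
    ``beta = 1``.
    """
    if K_j <= 0:
        raise ParameterError("K_j must be > 0")
    if n_total < 0:
        raise ParameterError("n_total must be >= 0")
    if not (0.0 <= beta <= 1.0):
        raise ParameterError("beta must be in [0, 1]")
    if not (0.0 < delta <= 1.0):
        raise ParameterError("delta must be in (0, 1]")
    return float(1.0 - delta + delta * _stay_bonus(n_total, K_j, beta))


def attraction_weight(
    i: int,
    j: int,
    k: int,
    state: PopulationState,
    cmap: CityMap,
    params: ModelParameters,
    beta: float,
) -> float:
    """Unnormalised weight of destination ``i`` for origin-``k`` movers in ``j``.

    ``(sum_{x != k} n_i^(x) + gamma n_i^(k))^beta * d_ij^-alpha *
    exp(-n_i / K_i)``.  At ``beta = 0`` the population factor is
    identically 1 (empty destinations included), recovering the
    distance-and-environment-only kernel.
    """
    if i == j:
        raise ParameterError("attraction weight is defined for i != j only")
    d = cmap.dist[i, j]
    if d == 0:
        raise DegenerateMapError(f"zero distance between cities {i} and {j}")
    n_i = state.n[i]
    total_i = float(n_i.sum())
    others = total_i - float(n_i[k])
    numer = others + params.gamma * float(n_i[k])
    pop_factor = 1.0 if beta == 0 else numer**beta
    return float(pop_factor * d ** (-params.alpha) * math.exp(-total_i / cmap.K[i]))


# ---------------------------------------------------------------------------
# kernel assembly
# ---------------------------------------------------------------------------


def _inverse_distance(cmap: CityMap, alpha: float) -> NDArray[np.float64]:
    """``d_ij^-alpha`` with a zero diagonal (the stay branch is separate)."""
    with np.errstate(divide="ignore"):
        Dinv = cmap.dist ** (-alpha)
    np.fill_diagonal(Dinv, 0.0)
    return Dinv


def _kernel_parts(
    n: NDArray[np.float64],
    beta: float,
    cmap: CityMap,
    params: ModelParameters,
    Dinv: NDArray[np.float64] | None = None,
):
    """Shared ingredients of all L origin kernels at one step.

    Returns ``(s, A, Dinv, Z)`` where ``s[j]`` is the staying probability of
    city ``j``, ``A[i, k]`` the distance-free attraction of destination ``i``
    for origin ``k``, and ``Z[j, k] = sum_i A[i, k] Dinv[i, j]`` the
    normalisation mass of column ``(j, k)``.
    """
    if Dinv is None:
        Dinv = _inverse_distance(cmap, params.alpha)
    n_tot = n.sum(axis=1)
    s = 1.0 - params.delta + params.delta * _stay_bonus(n_tot, cmap.K, beta)
    # social-tie numerator: others + gamma * own-origin, exactly non-negative
    base = (n_tot[:, None] - n) + params.gamma * n
    pop_factor = np.ones_like(base) if beta == 0 else base**beta
    A = pop_factor * np.exp(-n_tot / cmap.K)[:, None]
    Z = Dinv.T @ A
    return s, A, Dinv, Z


def build_kernels(
    state: PopulationState,
    t: int,
    cmap: CityMap,
    params: ModelParameters,
    Dinv: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    """All per-origin kernels for one step as an ``(L, L, L)`` array.

    ``W[k, i, j]`` is the probability that an origin-``k`` individual moves
    from city ``j`` to city ``i``.  Every column ``W[k, :, j]`` sums to one;
    a column whose off-diagonal raw weights all vanish (no admissible
    destination) collapses to the identity column so probability mass is
    conserved.
    """
    if state.L != cmap.L:
        raise ParameterError("state and map have different numbers of cities")
    L = state.L
    beta = float(beta_schedule(t, params.tau_beta))
    s, A, Dinv, Z = _kernel_parts(state.n, beta, cmap, params, Dinv)
    degenerate = Z <= 0.0  # (j, k): no admissible destination
    Zsafe = np.where(degenerate, 1.0, Z)
    # W[k, i, j] = (1 - s_j) * A[i, k] * Dinv[i, j] / Z[j, k]
    W = A.T[:, :, None] * Dinv[None, :, :]
    W *= (1.0 - s)[None, None, :] / Zsafe.T[:, None, :]
    diag = np.broadcast_to(s, (L, L)).copy()  # (k, j)
    if degenerate.any():
        jj, kk = np.nonzero(degenerate)
        W[kk, :, jj] = 0.0
        diag[kk, jj] = 1.0
    kidx = np.arange(L)
    W[:, kidx, kidx] = diag
    if not np.isfinite(W).all():
        k, i, j = np.argwhere(~np.isfinite(W))[0]
        raise NumericalError(
            f"non-finite kernel entry at origin={k}, dest={i}, src={j}, t={t}"
        )
    return W


def transition_kernel(
    state: PopulationState,
    t: int,
    k: int,
    cmap: CityMap,
    params: ModelParameters,
) -> TransitionKernel:
    """The column-stochastic kernel for origin ``k`` at time index ``t``."""
    W = build_kernels(state, t, cmap, params)
    beta = float(beta_schedule(t, params.tau_beta))
    s, A, Dinv, Z = _kernel_parts(state.n, beta, cmap, params)
    # off-diagonal w[i, j] = C[j] * raw_weight(i, j); C = (1 - s_j) / Z_jk
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(Z[:, k] > 0, (1.0 - s) / Z[:, k], 0.0)
    return TransitionKernel(w=W[k], C=C, origin=k, t=t, beta=beta)
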