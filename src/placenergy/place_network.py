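"""Energy-valued place-cell network: tuning, competitive learning, decoding.

Each of the N place cells carries a weight vector ``W_j`` in the unit cube
(its preferred normalized position), a per-spike energy constant ``C_j`` (nJ)
and a tuning width ``sigma_j``.  The cell's activity is expressed directly as
a firing *power*

    P_j = C_j * R_m * exp( - u_j^2 / (2 sigma_j^2) ),
    u_j = (1/n) * || X'/L - W_j ||,

where ``X'`` is the noisy sensory reading, ``L`` the arena side and ``n = 3``
the number of sensory inputs, so P_j is bounded by ``C_j * R_m`` (energy per
spike times maximum firing rate, in nW).

Learning is batch competitive: every cell whose power exceeds its threshold
``P_thr,j = p_thr_frac * C_j * R_m`` moves its weights a fraction ``mu``
toward the current normalized reading.  After learning, a frozen evaluation
pass defines each cell's place field (supra-threshold steps), its
power-weighted field center, and its total energy budget; the animal's
position is decoded as the power-weighted average of the responding cells'
field centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import Trajectory

__all__ = [
    "NetworkParams",
    "PlaceNetwork",
    "PowerResponse",
    "FieldSummary",
    "init_weights",
    "firing_power",
    "update_weights",
    "run_exploration",
    "evaluate_fields",
    "decode_location",
    "decode_trajectory",
]


@dataclass(frozen=True)
class NetworkParams:
    """Population and learning parameters.

    Defaults are the reference configuration: 200 cells, three boundary-
    distance inputs, 20 Hz peak rate, per-spike energies ``C_j ~ N(188, 10)``
    nJ, tuning widths ``sigma_j ~ N(0.03, 0.005)``, learning rate 0.001 and a
    response threshold at 30% of each cell's peak power.  ``sigma_w`` is the
    width of the sigmoidal map used to initialize weights; small values make
    the initial weight distribution bimodal toward 0/1, which seeds preferred
    positions near walls and corners.
    """

    n_cells: int = 200
    n_inputs: int = 3
    r_max: float = 20.0        # Hz
    c_mean: float = 188.0      # nJ per spike
    c_sd: float = 10.0
    sigma_mean: float = 0.03
    sigma_sd: float = 0.005
    mu: float = 0.001
    p_thr_frac: float = 0.3
    sigma_w: float = 0.1
    global_threshold: bool = False  # share one P_thr = frac * max_j C_j R_m

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one place cell")
        if self.r_max <= 0:
            raise ValueError("maximum firing rate must be positive")
        if not 0.0 < self.mu < 1.0:
            raise ValueError("learning rate must lie in (0, 1)")
        if not 0.0 < self.p_thr_frac < 1.0:
            raise ValueError("threshold fraction must lie in (0, 1)")
        if self.sigma_mean <= 0 or self.sigma_w <= 0:
            raise ValueError("tuning and initialization widths must be positive")


def init_weights(
    n_cells: int, sigma_w: float = 0.1, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Initial 3 x N weight matrix.

    Each entry is ``w = 1 / (1 + exp((gamma - 1/2) / (2 sigma_w^2)))`` with an
    independent ``gamma ~ U(0, 1)``, giving a distribution symmetric about
    0.5; for small ``sigma_w`` it is strongly bimodal toward 0 and 1.
    """
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    rng = np.random.default_rng(rng)
    gamma = rng.uniform(0.0, 1.0, size=(3, n_cells))
    return 1.0 / (1.0 + np.exp((gamma - 0.5) / (2.0 * sigma_w**2)))


@dataclass
class PlaceNetwork:
    """The learnable state: weights plus per-cell constants."""

    weights: np.ndarray  # (3, N), entries in [0, 1]
    c: np.ndarray        # (N,) per-spike energy, nJ
    sigma: np.ndarray    # (N,) tuning widths

    @property
    def n_cells(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def initialize(
        cls, params: NetworkParams, rng: np.random.Generator | int | None = None
    ) -> "PlaceNetwork":
        """Draw weights, per-spike energies and tuning widths.

        C_j and sigma_j are redrawn on the (practically impossible at the
        default means) event that a draw is non-positive.
        """
        rng = np.random.default_rng(rng)
        w = init_weights(params.n_cells, params.sigma_w, rng)

        def positive_normal(mean: float, sd: float, size: int) -> np.ndarray:
            x = rng.normal(mean, sd, size)
            while np.any(x <= 0):
                bad = x <= 0
                x[bad] = rng.normal(mean, sd, int(bad.sum()))
            return x

        return cls(
            weights=w,
            c=positive_normal(params.c_mean, params.c_sd, params.n_cells),
            sigma=positive_normal(params.sigma_mean, params.sigma_sd, params.n_cells),
        )

    def thresholds(self, params: NetworkParams) -> np.ndarray:
        """Per-cell response thresholds P_thr,j in nW."""
        if params.global_threshold:
            p_m = float(np.max(self.c)) * params.r_max
            return np.full(self.n_cells, params.p_thr_frac * p_m)
        return params.p_thr_frac * self.c * params.r_max


@dataclass
class PowerResponse:
    """Population response at one time step."""

    powers: np.ndarray        # (N,) nW
    response_set: np.ndarray  # indices with P_j > P_thr,j
    winner: int               # argmax of powers (lowest index on ties)


def _powers(network: PlaceNetwork, x_norm: np.ndarray, r_max: float) -> np.ndarray:
    """Firing powers for normalized readings; x_norm is (3,) or (T, 3)."""
    n = network.weights.shape[0]
    diff = np.atleast_2d(x_norm)[:, :, None] - network.weights[None, :, :]
    u = np.linalg.norm(diff, axis=1) / n
    p = network.c * r_max * np.exp(-(u**2) / (2.0 * network.sigma**2))
    return p if np.asarray(x_norm).ndim == 2 else p[0]


def firing_power(
    x_prime: np.ndarray,
    network: PlaceNetwork,
    arena_side: float,
    params: NetworkParams,
) -> PowerResponse:
    """Population response to one sensory reading (arena units)."""
    x_prime = np.asarray(x_prime, dtype=float)
    if np.any(x_prime < 0) or np.any(x_prime > arena_side):
        raise ValueError("reading outside the arena")
    p = _powers(network, x_prime / arena_side, params.r_max)
    thr = network.thresholds(params)
    return PowerResponse(
        powers=p,
        response_set=np.flatnonzero(p > thr),
        winner=int(np.argmax(p)),
    )


def update_weights(
    network: PlaceNetwork,
    response_set: np.ndarray,
    x_prime: np.ndarray,
    mu: float,
    arena_side: float,
) -> PlaceNetwork:
    """One batch competitive-learning step (in place; returns the network).

    Every cell in the response set moves its weight column a fraction ``mu``
    toward the normalized reading.  An empty response set degenerates to
    winner-take-all: only the single most active cell learns (callers pass
    the winner as a one-element set).
    """
    target = np.asarray(x_prime, dtype=float) / arena_side
    j = np.asarray(response_set, dtype=int)
    network.weights[:, j] += mu * (target[:, None] - network.weights[:, j])
    return network


def run_exploration(
    trajectory: Trajectory,
    readings: np.ndarray,
    network: PlaceNetwork,
    params: NetworkParams,
    arena_side: float,
) -> np.ndarray:
    """Drive learning along the trajectory; returns the (T, N) power log.

    At every step the population response to the reading is computed with the
    *current* weights, then all supra-threshold cells (or the winner alone if
    none crosses threshold) are updated.
    """
    readings = np.asarray(readings, dtype=float)
    if len(readings) != len(trajectory.positions):
        raise ValueError("trajectory and readings are misaligned")
    thr = network.thresholds(params)
    x_norm = readings / arena_side
    log = np.empty((len(readings), network.n_cells))
    for t in range(len(readings)):
        p = _powers(network, x_norm[t], params.r_max)
        log[t] = p
        j = np.flatnonzero(p > thr)
        if j.size == 0:
            j = np.array([int(np.argmax(p))])
        network.weights[:, j] += params.mu * (x_norm[t][:, None] - network.weights[:, j])
    return log


@dataclass
class FieldSummary:
    """Per-cell place-field statistics from a frozen evaluation pass."""

    field_size: np.ndarray    # (N,) supra-threshold step counts
    max_power: np.ndarray     # (N,) nW
    centers: np.ndarray       # (N, 3) arena units; NaN rows for silent cells
    total_energy: np.ndarray  # (N,) nJ
    field_steps: list = field(default_factory=list, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.field_size)


def evaluate_fields(
    network: PlaceNetwork,
    trajectory: Trajectory,
    readings: np.ndarray,
    params: NetworkParams,
    arena_side: float,
    dt_step: float = 1.0,
    powers: np.ndarray | None = None,
) -> FieldSummary:
    """Frozen-weights pass defining fields, centers and energy budgets.

    The field center is the power-weighted centroid of the readings over all
    steps; the place field is the set of supra-threshold steps; the total
    energy is the power integral with ``dt_step`` seconds per step (power in
    nW gives energy in nJ).  A cell with identically zero summed power has an
    undefined center, reported as a NaN row (empty field), never an error.
    Pass ``powers`` to reuse a precomputed (T, N) power log instead of
    re-evaluating.
    """
    readings = np.asarray(readings, dtype=float)
    if len(readings) != len(trajectory.positions):
        raise ValueError("trajectory and readings are misaligned")
    if powers is None:
        powers = _powers(network, readings / arena_side, params.r_max)
    thr = network.thresholds(params)
    above = powers > thr[None, :]
    psum = powers.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        centers = (powers.T @ readings) / psum[:, None]
    centers[psum == 0.0] = np.nan
    return FieldSummary(
        field_size=above.sum(axis=0),
        max_power=powers.max(axis=0),
        centers=centers,
        total_energy=powers.sum(axis=0) * dt_step,
        field_steps=[np.flatnonzero(above[:, j]) for j in range(network.n_cells)],
    )


def decode_location(response: PowerResponse, centers: np.ndarray) -> np.ndarray:
    """Population-vector position estimate from one response.

    The decoded position is the power-weighted average of the responding
    cells' field centers; with an empty response set it falls back to the
    winner's center.  Raises if the needed centers are undefined.
    """
    j = response.response_set
    if j.size == 0:
        j = np.array([response.winner])
    c = centers[j]
    if np.any(~np.isfinite(c)):
        raise ValueError("decoding requires defined centers for responding cells")
    w = response.powers[j]
    if w.sum() == 0.0:
        raise ValueError("all responding powers are zero; location undefined")
    return (w @ c) / w.sum()


def decode_trajectory(
    powers: np.ndarray,
    thresholds: np.ndarray,
    centers: np.ndarray,
) -> np.ndarray:
    """Vectorized decoding of a whole (T, N) power log."""
    above = powers > thresholds[None, :]
    # fall back to winner-only where nothing crosses threshold
    empty = ~above.any(axis=1)
    if np.any(empty):
        winners = np.argmax(powers[empty], axis=1)
        above[np.flatnonzero(empty), winners] = True
    w = np.where(above, powers, 0.0)
    finite = np.all(np.isfinite(centers), axis=1)
    if np.any(w[:, ~finite] > 0):
        raise ValueError("decoding requires defined centers for responding cells")
    denom = w.sum(axis=1, keepdims=True)
    if np.any(denom == 0.0):
        raise ValueError("a step has zero total responding power; location undefined")
    return (w @ np.nan_to_num(centers)) / denom
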