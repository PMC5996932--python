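"""Cube arena, random exploration and noisy boundary-distance sensing.

The simulated animal explores a cube of side ``L`` with fixed-length steps in
uniformly random directions.  Its position is encoded by the three distances
to the Left, Front and Down walls (the other three wall distances are
redundant), and what the network actually receives is a noise-corrupted
version of that distance triple: each component is scaled by ``1 + alpha*eta``
with ``eta ~ U(-1, 1)`` drawn independently per component, then clipped back
into the arena.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Arena", "Trajectory", "random_walk", "perceive", "perceive_trajectory"]


@dataclass(frozen=True)
class Arena:
    """A cube of side ``side`` (arena length units)."""

    side: float = 20.0

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("arena side must be positive")

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> bool:
        points = np.asarray(points)
        return bool(np.all(points >= -atol) and np.all(points <= self.side + atol))


@dataclass
class Trajectory:
    """An ordered exploration path of shape (n_steps + 1, 3)."""

    positions: np.ndarray
    step_length: float

    def __len__(self) -> int:
        return len(self.positions)


def _unit_vectors(rng: np.random.Generator, size: int) -> np.ndarray:
    v = rng.standard_normal((size, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_walk(
    arena: Arena,
    n_steps: int = 10_000,
    step_length: float = 1.0,
    start: np.ndarray | str = "random",
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Fixed-step random walk inside the arena.

    Each step moves ``step_length`` in a direction drawn uniformly on the unit
    sphere; directions that would leave the cube are redrawn, so every step
    has exactly the nominal length.  ``start`` is either a position or
    ``"random"`` (uniform over the cube).
    """
    if step_length >= arena.side:
        raise ValueError("step length must be smaller than the arena side")
    rng = np.random.default_rng(rng)
    if isinstance(start, str):
        if start != "random":
            raise ValueError(f"unknown start spec {start!r}")
        pos = rng.uniform(0.0, arena.side, size=3)
    else:
        pos = np.asarray(start, dtype=float)
        if not arena.contains(pos):
            raise ValueError("start position outside the arena")
    out = np.empty((n_steps + 1, 3))
    out[0] = pos
    for k in range(n_steps):
        while True:
            nxt = out[k] + step_length * _unit_vectors(rng, 1)[0]
            if arena.contains(nxt, atol=0.0):
                break
        out[k + 1] = nxt
    return Trajectory(positions=out, step_length=step_length)


def perceive(
    x: np.ndarray,
    alpha: float,
    rng: np.random.Generator | int | None = None,
    arena: Arena = Arena(),
) -> np.ndarray:
    """Noisy sensory reading of one position (distances to the L/F/D walls)."""
    return perceive_trajectory(np.asarray(x, float)[None, :], alpha, rng, arena)[0]


def perceive_trajectory(
    positions: np.ndarray,
    alpha: float,
    rng: np.random.Generator | int | None = None,
    arena: Arena = Arena(),
) -> np.ndarray:
    """Apply multiplicative sensory noise to a whole path at once.

    Each coordinate is scaled by ``1 + alpha * eta`` with an independent
    ``eta ~ U(-1, 1)`` per coordinate and per time step, then clipped to
    ``[0, side]`` so the normalized input stays inside the unit cube.
    """
    if alpha < 0:
        raise ValueError("sensory error rate alpha must be non-negative")
    positions = np.asarray(positions, dtype=float)
    if not arena.contains(positions):
        raise ValueError("positions outside the arena")
    rng = np.random.default_rng(rng)
    eta = rng.uniform(-1.0, 1.0, size=positions.shape)
    return np.clip(positions * (1.0 + alpha * eta), 0.0, arena.side)
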