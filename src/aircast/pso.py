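"""Particle swarm optimisation over a bounded box.

Canonical Kennedy–Eberhart dynamics: each particle carries a position x and
velocity V and is pulled toward its personal best y and the swarm's global
best ŷ,

    V <- w V + c1 r1 (y - x) + c2 r2 (ŷ - x),      x <- x + V,

with r1, r2 ~ U[0,1] per dimension, positions clipped to the bounds and
velocities clamped to a fraction of each dimension's range.  An alternative
update with a negated cognitive term and the roles of the two attractors
swapped is available via ``use_printed_update`` for comparison; it is not
recommended (it repels particles from the global best).

Used here to select the forecaster's integer hyperparameters (window
length, LSTM cell count): internally positions stay continuous and are
rounded only at fitness evaluation and in the final report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 20
    iterations: int = 30
    inertia: float = 0.8
    cognitive: float = 2.0
    social: float = 2.0
    bounds: tuple[tuple[float, float], ...] = ((1, 20), (1, 100))
    velocity_clamp: float = 0.5  # fraction of each dimension's range
    seed: int = 0
    use_printed_update: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.inertia <= 1.0:
            raise ValueError("inertia must be in (0, 1]")
        if self.cognitive < 0 or self.social < 0:
            raise ValueError("cognitive and social coefficients must be non-negative")
        if len(self.bounds) == 0:
            raise ValueError("bounds must be non-empty")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"each bound must satisfy low < high, got ({lo}, {hi})")
        if self.swarm_size < 1 or self.iterations < 1:
            raise ValueError("swarm_size and iterations must be at least 1")


@dataclass
class Swarm:
    """Mutable swarm state: positions, velocities, personal/global bests."""

    positions: np.ndarray      # (m, d)
    velocities: np.ndarray     # (m, d)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # (m,)
    gbest_position: np.ndarray
    gbest_fitness: float


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    out = np.empty(len(positions))
    for i, x in enumerate(positions):
        try:
            f = float(fitness_fn(x))
        except FloatingPointError:
            f = np.nan
        if not np.isfinite(f):
            logger.warning("non-finite fitness at %s; treating as +inf", x)
            f = np.inf
        out[i] = f
    return out


def init_swarm(fitness_fn, config: PSOConfig, rng: np.random.Generator) -> Swarm:
    """Uniform random positions within bounds, zero initial velocities."""
    lo = np.array([b[0] for b in config.bounds], dtype=float)
    hi = np.array([b[1] for b in config.bounds], dtype=float)
    pos = rng.uniform(lo, hi, size=(config.swarm_size, len(config.bounds)))
    vel = np.zeros_like(pos)
    fit = _evaluate(fitness_fn, pos)
    best = int(np.argmin(fit))
    return Swarm(pos, vel, pos.copy(), fit, pos[best].copy(), float(fit[best]))


def step(swarm: Swarm, fitness_fn, config: PSOConfig, rng: np.random.Generator) -> Swarm:
    """One synchronous velocity/position/best update (in place)."""
    lo = np.array([b[0] for b in config.bounds], dtype=float)
    hi = np.array([b[1] for b in config.bounds], dtype=float)
    vmax = config.velocity_clamp * (hi - lo)
    r1 = rng.uniform(size=swarm.positions.shape)
    r2 = rng.uniform(size=swarm.positions.shape)
    if config.use_printed_update:
        # Literal transcription of the published update: negated pull toward
        # the global best, personal best on the social coefficient.
        swarm.velocities = (
            config.inertia * swarm.velocities
            - config.cognitive * r1 * (swarm.gbest_position - swarm.positions)
            + config.social * r2 * (swarm.pbest_positions - swarm.positions)
        )
    else:
        swarm.velocities = (
            config.inertia * swarm.velocities
            + config.cognitive * r1 * (swarm.pbest_positions - swarm.positions)
            + config.social * r2 * (swarm.gbest_position - swarm.positions)
        )
    np.clip(swarm.velocities, -vmax, vmax, out=swarm.velocities)
    swarm.positions = np.clip(swarm.positions + swarm.velocities, lo, hi)

    fit = _evaluate(fitness_fn, swarm.positions)
    improved = fit < swarm.pbest_fitness  # strict: ties keep the incumbent
    swarm.pbest_positions[improved] = swarm.positions[improved]
    swarm.pbest_fitness[improved] = fit[improved]
    best = int(np.argmin(swarm.pbest_fitness))
    if swarm.pbest_fitness[best] < swarm.gbest_fitness:
        swarm.gbest_fitness = float(swarm.pbest_fitness[best])
        swarm.gbest_position = swarm.pbest_positions[best].copy()
    return swarm


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)  # gbest per iteration


def optimize(fitness_fn, config: PSOConfig) -> PSOResult:
    """Run the swarm for ``config.iterations`` steps; history is the global
    best after each iteration (monotone non-increasing by construction)."""
    rng = np.random.default_rng(config.seed)
    swarm = init_swarm(fitness_fn, config, rng)
    history: list[float] = []
    for _ in range(config.iterations):
        step(swarm, fitness_fn, config, rng)
        history.append(swarm.gbest_fitness)
    return PSOResult(swarm.gbest_position.copy(), swarm.gbest_fitness, history)


#: Search box for the forecaster's hyperparameters: window length 1-20 days,
#: LSTM cell count 1-100.
HYPERPARAMETER_BOUNDS: tuple[tuple[float, float], ...] = ((1, 20), (1, 100))


def encode_hyperparameters(position: np.ndarray) -> tuple[int, int]:
    """Map a continuous swarm position to integer (window, cells).

    Round-half-away-from-zero to nearest integer, then clip to the search
    ranges window in [1, 20] and cells in [1, 100].
    """
    pos = np.asarray(position, dtype=float)
    n = int(np.clip(np.floor(pos[0] + 0.5), 1, 20))
    cells = int(np.clip(np.floor(pos[1] + 0.5), 1, 100))
    return n, cells
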