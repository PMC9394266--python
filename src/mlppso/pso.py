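"""Global-best particle swarm optimization over real vectors.

A swarm of candidate solutions moves through the search space under three
forces: inertia (w), attraction toward each particle's own best position
(cognitive, c1) and attraction toward the best position any particle has
found (social, c2):

    v_{t+1} = w * v_t + c1 * r1 * (pbest_t - x_t) + c2 * r2 * (gbest_t - x_t)
    x_{t+1} = x_t + v_{t+1}

r1, r2 are either drawn fresh per dimension, per particle, per update from
[0, 1) (``r_mode="random"``, canonical PSO) or held at fixed constants
(``r_mode="fixed"``, which makes a whole run a deterministic function of
the initialization seed).  Star topology only: every particle sees the one
global best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]

R_RANDOM = "random"
R_FIXED = "fixed"


@dataclass(frozen=True)
class PSOConfig:
    """Controlling parameters.

    The classifier defaults: swarm of 100 particles, 50 iterations, inertia
    w=0.9, cognitive c1=0.5, social c2=0.3; fixed-mode draws r1=0.4, r2=0.5.
    The run stops early once the global best fitness falls to error_limit.
    """

    swarm_size: int = 100
    max_iterations: int = 50
    w: float = 0.9
    c1: float = 0.5
    c2: float = 0.3
    r_mode: str = R_RANDOM
    r1_fixed: float = 0.4
    r2_fixed: float = 0.5
    error_limit: float = 1e-3
    init_position_range: tuple[float, float] = (-1.0, 1.0)
    init_velocity_range: tuple[float, float] = (-0.1, 0.1)
    velocity_clamp: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if min(self.w, self.c1, self.c2) < 0:
            raise ValueError("w, c1, c2 must be nonnegative")
        if self.r_mode not in (R_RANDOM, R_FIXED):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")
        for r in (self.r1_fixed, self.r2_fixed):
            if not 0.0 <= r < 1.0:
                raise ValueError("fixed r values must lie in [0, 1)")
        for lo, hi in (self.init_position_range, self.init_velocity_range):
            if not lo < hi:
                raise ValueError("init range low must be < high")
        if self.error_limit < 0:
            raise ValueError("error_limit must be nonnegative")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["init_position_range"] = list(self.init_position_range)
        d["init_velocity_range"] = list(self.init_velocity_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PSOConfig":
        d = dict(d)
        d["init_position_range"] = tuple(d["init_position_range"])
        d["init_velocity_range"] = tuple(d["init_velocity_range"])
        return cls(**d)


@dataclass
class SwarmState:
    """Full search state: per-particle positions/velocities/personal bests,
    the global best, and the per-iteration global-best fitness history."""

    positions: np.ndarray       # (S, D)
    velocities: np.ndarray      # (S, D)
    pbest_positions: np.ndarray # (S, D)
    pbest_fitness: np.ndarray   # (S,)
    gbest_position: np.ndarray  # (D,)
    gbest_fitness: float
    iteration: int = 0
    history: list[float] = field(default_factory=list)

    @property
    def swarm_size(self) -> int:
        return self.positions.shape[0]


def _safe_eval(objective: Objective, x: np.ndarray) -> float:
    f = float(objective(x))
    if not np.isfinite(f):
        logger.warning("non-finite fitness %r treated as +inf", f)
        return np.inf
    return f


def initialize_swarm(
    config: PSOConfig, dim: int, objective: Objective, rng: np.random.Generator | None = None
) -> SwarmState:
    """Uniform random positions and velocities within the configured ranges;
    every particle evaluated once, personal bests set to the initial points,
    global best to the best of them."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.init_position_range
    positions = rng.uniform(lo, hi, size=(config.swarm_size, dim))
    vlo, vhi = config.init_velocity_range
    velocities = rng.uniform(vlo, vhi, size=(config.swarm_size, dim))
    fitness = np.empty(config.swarm_size)
    for i in range(config.swarm_size):
        f = float(objective(positions[i]))
        if not np.isfinite(f):
            raise ValueError(f"non-finite objective at initial particle {i}: {f!r}")
        fitness[i] = f
    best = int(np.argmin(fitness))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness,
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fitness[best]),
        iteration=0,
        history=[float(fitness[best])],
    )


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    config: PSOConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One velocity update for one particle, elementwise.

    In random mode r1 and r2 are freshly sampled per dimension from [0, 1)
    (r1 first, then r2); in fixed mode they are the configured constants.
    """
    if config.r_mode == R_RANDOM:
        if rng is None:
            raise ValueError("random r_mode requires an rng")
        r1 = rng.random(velocity.shape)
        r2 = rng.random(velocity.shape)
    else:
        r1 = config.r1_fixed
        r2 = config.r2_fixed
    v = (
        config.w * velocity
        + config.c1 * r1 * (pbest - position)
        + config.c2 * r2 * (gbest - position)
    )
    if config.velocity_clamp is not None:
        v = np.clip(v, -config.velocity_clamp, config.velocity_clamp)
    return v


def update_position(position: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    """x_{t+1} = x_t + v_{t+1}; positions are unbounded."""
    return position + velocity


def step(
    state: SwarmState, objective: Objective, config: PSOConfig, rng: np.random.Generator | None = None
) -> SwarmState:
    """One swarm iteration, mutating and returning ``state``.

    Particle order is fixed (index order); for each particle: update
    velocity, update position, evaluate, update its personal best, then the
    global best (so later particles in the same iteration already see an
    improved global best).  A non-finite fitness is treated as +inf and can
    never become a best.
    """
    for i in range(state.swarm_size):
        v = update_velocity(
            state.velocities[i],
            state.positions[i],
            state.pbest_positions[i],
            state.gbest_position,
            config,
            rng,
        )
        state.velocities[i] = v
        state.positions[i] = update_position(state.positions[i], v)
        f = _safe_eval(objective, state.positions[i])
        if f < state.pbest_fitness[i]:
            state.pbest_fitness[i] = f
            state.pbest_positions[i] = state.positions[i].copy()
            if f < state.gbest_fitness:
                state.gbest_fitness = f
                state.gbest_position = state.positions[i].copy()
    state.iteration += 1
    state.history.append(state.gbest_fitness)
    return state


@dataclass
class PSOResult:
    position: np.ndarray
    fitness: float
    history: list[float]
    iterations: int


def optimize(objective: Objective, dim: int, config: PSOConfig) -> PSOResult:
    """Run the swarm until max_iterations or gbest fitness <= error_limit.

    history[0] is the initial global best; one entry is appended per
    iteration, and the sequence is non-increasing by construction.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(config, dim, objective, rng)
    while state.iteration < config.max_iterations and state.gbest_fitness > config.error_limit:
        step(state, objective, config, rng)
    return PSOResult(
        position=state.gbest_position.copy(),
        fitness=state.gbest_fitness,
        history=list(state.history),
        iterations=state.iteration,
    )
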