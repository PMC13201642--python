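"""Particle swarm optimization with constant inertia, plus segmentation adapters.

Velocity update: v' = theta*v + alpha*eps1*(g* - x) + beta*eps2*(x* - x),
with eps1, eps2 drawn uniformly in [0, 1] per dimension per update and each
velocity component clamped to [-v_max, v_max]. Positions advance by v'*dt and
reflect at the search bounds. Particles initialize uniformly over the bounds
with zero initial velocity; iteration stops at max_iter or after the relative
global-best improvement stays below a stagnation tolerance for 15 consecutive
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wmhkit import metrics, preprocess
from wmhkit.types import ConfigurationError, EmptyClassError, Volume, WMHKitError, as_bool_mask

STAGNATION_WINDOW = 15


class NonFiniteObjectiveError(WMHKitError):
    """The objective returned a non-finite value; carries the position."""

    def __init__(self, position: np.ndarray, value: float):
        self.position = np.asarray(position)
        self.value = value
        super().__init__(f"objective returned {value} at position {self.position}")


@dataclass
class SwarmConfig:
    """Hyperparameters of the swarm.

    alpha and beta are the global- and personal-best acceleration coefficients
    (defaults 2.0); theta is the constant inertia weight in [0, 1] (default
    0.7); v_max caps each velocity component; delta_t is the (dimensionless)
    time increment.
    """

    bounds: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    n_particles: int = 20
    alpha: float = 2.0
    beta: float = 2.0
    theta: float = 0.7
    v_max: float = 1.0
    delta_t: float = 1.0
    max_iter: int = 100
    tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError("theta must lie in [0, 1]")
        if self.v_max <= 0:
            raise ConfigurationError("v_max must be > 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigurationError(f"each bound needs lo < hi, got ({lo}, {hi})")

    @property
    def n_dims(self) -> int:
        return len(self.bounds)


@dataclass
class SwarmState:
    """Positions, velocities, and best-so-far bookkeeping."""

    positions: np.ndarray
    velocities: np.ndarray
    personal_best_positions: np.ndarray
    personal_best_values: np.ndarray
    global_best_position: np.ndarray
    global_best_value: float
    iteration: int = 0


@dataclass
class OptimizeResult:
    position: np.ndarray
    value: float
    history: list[float]
    state: SwarmState


def update_velocity(
    state: SwarmState,
    particle_index: int,
    config: SwarmConfig,
    random_pair: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One particle's new velocity; ``random_pair`` injects (eps1, eps2) for tests."""
    x = state.positions[particle_index]
    v = state.velocities[particle_index]
    p = state.personal_best_positions[particle_index]
    g = state.global_best_position
    if random_pair is None:
        rng = rng if rng is not None else np.random.default_rng()
        eps1 = rng.uniform(size=x.shape)
        eps2 = rng.uniform(size=x.shape)
    else:
        eps1, eps2 = (np.broadcast_to(np.asarray(e, dtype=float), x.shape) for e in random_pair)
    v_new = config.theta * v + config.alpha * eps1 * (g - x) + config.beta * eps2 * (p - x)
    return np.clip(v_new, -config.v_max, config.v_max)


def _reflect(x: np.ndarray, bounds) -> np.ndarray:
    """Reflect positions at finite bounds until feasible."""
    x = x.copy()
    for d, (lo, hi) in enumerate(bounds):
        if not (np.isfinite(lo) and np.isfinite(hi)):
            continue
        span = hi - lo
        val = x[d]
        # fold into [lo, lo + 2*span) then mirror the upper half
        val = (val - lo) % (2 * span)
        x[d] = lo + (val if val <= span else 2 * span - val)
    return x


def step_position(x: np.ndarray, v: np.ndarray, config: SwarmConfig) -> np.ndarray:
    """x' = x + v*dt, reflected at the search bounds."""
    return _reflect(np.asarray(x, dtype=float) + np.asarray(v, dtype=float) * config.delta_t,
                    config.bounds)


def _evaluate(objective, x: np.ndarray) -> float:
    value = float(objective(x))
    if not np.isfinite(value):
        raise NonFiniteObjectiveError(x, value)
    return value


def optimize(objective, config: SwarmConfig) -> OptimizeResult:
    """Minimize ``objective`` over ``config.bounds``.

    Fully reproducible under a fixed seed; the returned history is the
    global-best value after each iteration (monotone non-increasing).
    """
    rng = np.random.default_rng(config.seed)
    dims = config.n_dims
    lows = np.array([lo for lo, _ in config.bounds])
    highs = np.array([hi for _, hi in config.bounds])
    positions = rng.uniform(lows, highs, size=(config.n_particles, dims))
    velocities = np.zeros_like(positions)

    values = np.array([_evaluate(objective, p) for p in positions])
    best_idx = int(np.argmin(values))
    state = SwarmState(
        positions=positions,
        velocities=velocities,
        personal_best_positions=positions.copy(),
        personal_best_values=values.copy(),
        global_best_position=positions[best_idx].copy(),
        global_best_value=float(values[best_idx]),
    )

    history = [state.global_best_value]
    stagnant = 0
    for _ in range(config.max_iter):
        previous_best = state.global_best_value
        for i in range(config.n_particles):
            v_new = update_velocity(state, i, config, rng=rng)
            x_new = step_position(state.positions[i], v_new, config)
            state.velocities[i] = v_new
            state.positions[i] = x_new
            value = _evaluate(objective, x_new)
            if value < state.personal_best_values[i]:
                state.personal_best_values[i] = value
                state.personal_best_positions[i] = x_new.copy()
                if value < state.global_best_value:
                    state.global_best_value = value
                    state.global_best_position = x_new.copy()
        state.iteration += 1
        history.append(state.global_best_value)
        improvement = previous_best - state.global_best_value
        rel = improvement / max(abs(previous_best), 1e-30)
        stagnant = stagnant + 1 if rel < config.tol else 0
        if stagnant >= STAGNATION_WINDOW:
            break
    return OptimizeResult(
        position=state.global_best_position.copy(),
        value=state.global_best_value,
        history=history,
        state=state,
    )


@dataclass
class SegmentationSearchSpace:
    """Bounds of the tunable candidate-lesion parameters."""

    k: tuple[float, float] = (0.5, 4.0)
    structuring_radius: tuple[int, int] = (1, 2)


def optimize_segmentation(
    volume: Volume,
    brain_mask,
    reference_mask,
    search_space: SegmentationSearchSpace | None = None,
    config: SwarmConfig | None = None,
    weight_map: np.ndarray | None = None,
) -> tuple[preprocess.SegmentationParams, float, list[float]]:
    """Tune (k, structuring radius) of threshold + opening against a reference.

    The objective is the (optionally weighted) Dice loss of
    ``morph_open(candidate_wmh(volume, brain_mask, k), radius)`` against the
    reference mask; the continuous radius coordinate is rounded to the nearest
    integer within its bounds. Returns the tuned parameters, the best loss,
    and the per-iteration best-loss history.
    """
    brain_mask = as_bool_mask(brain_mask)
    reference = as_bool_mask(reference_mask)
    if reference.shape != volume.shape:
        raise ConfigurationError("reference mask must align with the volume")
    if not reference.any():
        raise EmptyClassError("optimize_segmentation: empty reference mask")
    space = search_space if search_space is not None else SegmentationSearchSpace()
    r_lo, r_hi = space.structuring_radius

    def objective(x: np.ndarray) -> float:
        k = float(x[0])
        radius = int(np.clip(round(float(x[1])), r_lo, r_hi))
        predicted = preprocess.morph_open(
            preprocess.candidate_wmh(volume, brain_mask, k), radius
        )
        return metrics.dice_loss(predicted.astype(float), reference, weights=weight_map)

    if config is None:
        config = SwarmConfig()
    k_lo, k_hi = space.k
    if k_lo == k_hi and r_lo == r_hi:
        # degenerate search space: a single point, returned with its loss
        point = np.array([k_lo, float(r_lo)])
        value = objective(point)
        params = preprocess.SegmentationParams(k=k_lo, structuring_radius=r_lo)
        return params, value, [value]
    if k_lo == k_hi:
        k_lo, k_hi = k_lo - 1e-9, k_hi + 1e-9
    config = SwarmConfig(
        bounds=[(k_lo, k_hi), (r_lo - 0.49, r_hi + 0.49)],
        n_particles=config.n_particles,
        alpha=config.alpha,
        beta=config.beta,
        theta=config.theta,
        v_max=config.v_max,
        delta_t=config.delta_t,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=config.seed,
    )
    result = optimize(objective, config)
    params = preprocess.SegmentationParams(
        k=float(result.position[0]),
        structuring_radius=int(np.clip(round(float(result.position[1])), r_lo, r_hi)),
    )
    return params, result.value, result.history
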