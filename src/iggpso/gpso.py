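"""Grouping binary particle-swarm wrapper search.

Each particle encodes a candidate feature subset as a bit vector over the
*active pool* — initially the top feature group, grown by appending the
next group whenever the swarm stagnates.  Velocities follow the canonical
PSO update

    v' = w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),    |v'| <= v_max

and bits are resampled through the sigmoid transfer x ~ Bernoulli(1/(1+e^-v)).

Two fitness functions drive the search.  Inside a pool phase the swarm
maximizes the in-group fitness, the cross-validated accuracy of the
selected subset.  When a phase ends (stagnation for ``patience`` iterations
or ``max_iter`` reached) the phase's best subset is scored by the out-group
fitness

    lambda * ACC - (1 - lambda) * |subset| / n_features

which trades accuracy against feature scale, and the best phase result over
the whole run is returned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .dataio import ExpressionDataset
from .evaluation import EvalProtocol, evaluate_subset
from .grouping import FeatureGroups

__all__ = [
    "GPSOConfig",
    "Particle",
    "SwarmState",
    "FitnessRecord",
    "SelectionResult",
    "init_swarm",
    "update_velocity",
    "update_position",
    "in_group_fitness",
    "out_group_fitness",
    "run_gpso",
]


@dataclass
class GPSOConfig:
    """Swarm hyperparameters; defaults are canonical binary-PSO settings."""

    w: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 6.0
    swarm_size: int = 20
    max_iter: int = 50
    lambda_: float = 0.9
    patience: int = 10
    seed: int = 0
    transfer: str = "sigmoid"
    use_cache: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must lie in [0, 1]")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.transfer != "sigmoid":
            raise ValueError(f"unknown transfer function {self.transfer!r}")


@dataclass
class Particle:
    position: np.ndarray  # bits over the active pool, 1 = feature selected
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = -np.inf


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    active_pool: np.ndarray  # dataset feature indices currently searchable
    groups_consumed: int
    iteration: int = 0
    stagnation: int = 0


@dataclass
class FitnessRecord:
    acc: float
    subset_size: int
    in_fitness: float
    out_fitness: float


@dataclass
class SelectionResult:
    """Final subset of a wrapper run with its score and search history."""

    selected: np.ndarray
    acc: float
    fs: int
    history: list[dict]
    config_snapshot: dict
    seed: int
    feature_ids: list[str] = field(default_factory=list)
    feature_ig: list[float] = field(default_factory=list)
    feature_group: list[int] = field(default_factory=list)

    def config_hash(self) -> str:
        payload = json.dumps(self.config_snapshot, sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]

    def selection_rows(self) -> list[tuple[str, float, int]]:
        """(feature_id, ig, group_index) per selected feature, for export."""
        ids = self.feature_ids or [str(i) for i in self.selected]
        igs = self.feature_ig or [float("nan")] * len(self.selected)
        grp = self.feature_group or [-1] * len(self.selected)
        return list(zip(ids, igs, grp))


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def _repair_all_zero(position: np.ndarray, velocity: np.ndarray, rng) -> None:
    """An empty subset is not evaluable; set one bit in place."""
    if position.any():
        return
    if velocity is None:
        position[rng.integers(len(position))] = 1
    else:
        position[int(np.argmax(velocity))] = 1


def init_swarm(
    pool_size: int,
    config: GPSOConfig,
    rng: np.random.Generator,
    fitness: Callable[[np.ndarray], float] | None = None,
    active_pool: np.ndarray | None = None,
) -> SwarmState:
    """Random initial swarm: Bernoulli(0.5) bits, uniform velocities.

    When ``fitness`` is supplied the initial positions are evaluated so the
    personal bests and the global best reflect the starting population;
    otherwise the bests are placeholders refreshed on the first iteration.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    particles: list[Particle] = []
    for _ in range(config.swarm_size):
        position = (rng.random(pool_size) < 0.5).astype(np.int8)
        if not position.any():
            position[rng.integers(pool_size)] = 1
        velocity = rng.uniform(-config.v_max, config.v_max, pool_size)
        particles.append(
            Particle(
                position=position,
                velocity=velocity,
                pbest_position=position.copy(),
            )
        )
    if fitness is not None:
        for p in particles:
            p.pbest_fitness = fitness(p.position)
    best = max(range(len(particles)), key=lambda i: particles[i].pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=particles[best].position.copy(),
        gbest_fitness=particles[best].pbest_fitness,
        active_pool=(
            np.arange(pool_size, dtype=np.int64)
            if active_pool is None
            else np.asarray(active_pool, dtype=np.int64)
        ),
        groups_consumed=1,
    )


def update_velocity(
    particle: Particle,
    gbest_position: np.ndarray,
    config: GPSOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inertia + cognitive + social pull, clamped to [-v_max, v_max]."""
    r1 = rng.random()
    r2 = rng.random()
    x = particle.position.astype(float)
    v = (
        config.w * particle.velocity
        + config.c1 * r1 * (particle.pbest_position.astype(float) - x)
        + config.c2 * r2 * (gbest_position.astype(float) - x)
    )
    return np.clip(v, -config.v_max, config.v_max)


def update_position(
    particle: Particle, config: GPSOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sigmoid-transfer Bernoulli resampling of every bit; empty repaired."""
    bits = (rng.random(len(particle.velocity)) < _sigmoid(particle.velocity)).astype(
        np.int8
    )
    _repair_all_zero(bits, particle.velocity, rng)
    return bits


def out_group_fitness(
    acc: float, subset_size: int, total_features: int, lambda_: float
) -> float:
    """lambda * ACC - (1 - lambda) * subset_size / total_features."""
    if total_features <= 0:
        raise ValueError("total_features must be positive")
    if not 1 <= subset_size <= total_features:
        raise ValueError("subset_size must lie in [1, total_features]")
    return lambda_ * acc - (1.0 - lambda_) * subset_size / total_features


class _FitnessCache:
    """Memoizes CV accuracy per selected-feature set; purely transparent."""

    def __init__(
        self,
        dataset: ExpressionDataset,
        protocol: EvalProtocol,
        enabled: bool = True,
    ) -> None:
        self._dataset = dataset
        self._protocol = protocol
        self._folds = protocol.fold_indices(dataset.labels)
        self._enabled = enabled
        self._store: dict[bytes, float] = {}
        self.evaluations = 0

    def acc(self, subset: np.ndarray) -> float:
        key = np.sort(subset).astype(np.int64).tobytes()
        if self._enabled and key in self._store:
            return self._store[key]
        value = evaluate_subset(self._dataset, subset, self._protocol, folds=self._folds)
        self.evaluations += 1
        if self._enabled:
            self._store[key] = value
        return value


def in_group_fitness(
    position: np.ndarray,
    active_pool: np.ndarray,
    dataset: ExpressionDataset,
    protocol: EvalProtocol,
    lambda_: float = 1.0,
    total_features: int | None = None,
    _cache: _FitnessCache | None = None,
) -> FitnessRecord:
    """Accuracy of the subset encoded by ``position`` over the active pool."""
    position = np.asarray(position)
    if not position.any():
        raise ValueError("all-zero position: caller must repair before evaluating")
    subset = np.asarray(active_pool)[position.astype(bool)]
    acc = (
        _cache.acc(subset)
        if _cache is not None
        else evaluate_subset(dataset, subset, protocol)
    )
    total = total_features if total_features is not None else dataset.n_features
    return FitnessRecord(
        acc=acc,
        subset_size=int(subset.size),
        in_fitness=acc,
        out_fitness=out_group_fitness(acc, int(subset.size), total, lambda_),
    )


def run_gpso(
    groups: FeatureGroups,
    dataset: ExpressionDataset,
    config: GPSOConfig,
    protocol: EvalProtocol,
) -> SelectionResult:
    """Grouped swarm search over the feature groups.

    The active pool starts as the first (highest-IG) group.  Within a pool
    phase the swarm maximizes in-group fitness; the phase ends when the
    global best stalls for ``patience`` iterations or after ``max_iter``
    iterations.  At each phase end the phase best is scored out-group; if
    unconsumed groups remain, the next group's features join the pool
    (fresh random bits/velocities in the new dimensions, bests extended
    with zeros) and the search continues.  The subset with the best
    out-group fitness over all phases is returned.
    """
    if groups.k < 1 or groups.n_features == 0:
        raise ValueError("empty feature groups")
    total_features = groups.n_features
    rng = np.random.default_rng(config.seed)
    cache = _FitnessCache(dataset, protocol, enabled=config.use_cache)

    pool = groups.groups[0].copy()

    def fit(position: np.ndarray, active: np.ndarray) -> FitnessRecord:
        return in_group_fitness(
            position, active, dataset, protocol,
            lambda_=config.lambda_, total_features=total_features, _cache=cache,
        )

    swarm = init_swarm(
        len(pool), config, rng,
        fitness=lambda pos: fit(pos, pool).in_fitness,
        active_pool=pool,
    )

    history: list[dict] = []
    best_out = -np.inf
    best_subset: np.ndarray | None = None
    best_acc = float("nan")
    phase = 1

    while True:
        phase_iter = 0
        swarm.stagnation = 0
        while phase_iter < config.max_iter and swarm.stagnation < config.patience:
            improved = False
            for particle in swarm.particles:
                particle.velocity = update_velocity(
                    particle, swarm.gbest_position, config, rng
                )
                particle.position = update_position(particle, config, rng)
                record = fit(particle.position, swarm.active_pool)
                if record.in_fitness > particle.pbest_fitness:
                    particle.pbest_fitness = record.in_fitness
                    particle.pbest_position = particle.position.copy()
                if record.in_fitness > swarm.gbest_fitness:
                    swarm.gbest_fitness = record.in_fitness
                    swarm.gbest_position = particle.position.copy()
                    improved = True
            phase_iter += 1
            swarm.iteration += 1
            swarm.stagnation = 0 if improved else swarm.stagnation + 1
            history.append(
                {
                    "phase": phase,
                    "iteration": swarm.iteration,
                    "gbest_in_fitness": swarm.gbest_fitness,
                    "active_pool_size": len(swarm.active_pool),
                    "gbest_subset_size": int(swarm.gbest_position.sum()),
                }
            )

        # phase over: score the phase best out-group
        phase_subset = swarm.active_pool[swarm.gbest_position.astype(bool)]
        phase_acc = cache.acc(phase_subset)
        phase_out = out_group_fitness(
            phase_acc, len(phase_subset), total_features, config.lambda_
        )
        history.append(
            {
                "phase": phase,
                "iteration": swarm.iteration,
                "out_fitness": phase_out,
                "acc": phase_acc,
                "subset_size": len(phase_subset),
            }
        )
        if phase_out > best_out:
            best_out = phase_out
            best_subset = phase_subset.copy()
            best_acc = phase_acc

        if swarm.groups_consumed >= groups.k:
            break

        # stagnation-triggered expansion: append the next group's features
        new_group = groups.groups[swarm.groups_consumed]
        grown = len(new_group)
        swarm.active_pool = np.concatenate([swarm.active_pool, new_group])
        swarm.groups_consumed += 1
        for particle in swarm.particles:
            fresh_bits = (rng.random(grown) < 0.5).astype(np.int8)
            fresh_vel = rng.uniform(-config.v_max, config.v_max, grown)
            particle.position = np.concatenate([particle.position, fresh_bits])
            particle.velocity = np.concatenate([particle.velocity, fresh_vel])
            particle.pbest_position = np.concatenate(
                [particle.pbest_position, np.zeros(grown, dtype=np.int8)]
            )
        swarm.gbest_position = np.concatenate(
            [swarm.gbest_position, np.zeros(grown, dtype=np.int8)]
        )
        phase += 1

    assert best_subset is not None
    selected = np.sort(best_subset)
    snapshot = asdict(config)
    return SelectionResult(
        selected=selected,
        acc=float(best_acc),
        fs=int(selected.size),
        history=history,
        config_snapshot=snapshot,
        seed=config.seed,
        feature_ids=[dataset.feature_ids[j] for j in selected],
        feature_ig=[groups.ig_of.get(int(j), float("nan")) for j in selected],
        feature_group=[
            next(
                (g for g, members in enumerate(groups.groups) if int(j) in members),
                -1,
            )
            for j in selected
        ],
    )
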