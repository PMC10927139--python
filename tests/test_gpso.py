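"""Binary swarm mechanics and the grouped search as a whole."""

import numpy as np
import pytest

from iggpso import (
    EvalProtocol,
    GPSOConfig,
    out_group_fitness,
    pso_select,
    run_gpso,
)
from iggpso.gpso import (
    Particle,
    in_group_fitness,
    init_swarm,
    update_position,
    update_velocity,
)
from iggpso.grouping import FeatureGroups, partition_features
from iggpso.infogain import RankedFeatures


def test_config_validation():
    with pytest.raises(ValueError):
        GPSOConfig(lambda_=1.5)
    with pytest.raises(ValueError):
        GPSOConfig(swarm_size=1)
    with pytest.raises(ValueError):
        GPSOConfig(v_max=0.0)


def test_init_swarm_shapes_and_ranges():
    config = GPSOConfig(swarm_size=5, v_max=4.0, seed=0)
    swarm = init_swarm(10, config, np.random.default_rng(0))
    assert len(swarm.particles) == 5
    for p in swarm.particles:
        assert p.position.shape == (10,)
        assert p.velocity.shape == (10,)
        assert set(np.unique(p.position)) <= {0, 1}
        assert np.all(np.abs(p.velocity) <= 4.0)
        assert p.position.any()  # all-zero repaired


def test_init_swarm_deterministic():
    config = GPSOConfig(swarm_size=4)
    a = init_swarm(8, config, np.random.default_rng(123))
    b = init_swarm(8, config, np.random.default_rng(123))
    for pa, pb in zip(a.particles, b.particles):
        assert np.array_equal(pa.position, pb.position)
        assert np.allclose(pa.velocity, pb.velocity)


def test_init_swarm_pool_of_one_repairs_to_selected():
    swarm = init_swarm(1, GPSOConfig(swarm_size=6), np.random.default_rng(5))
    for p in swarm.particles:
        assert p.position.tolist() == [1]


def _particle(x, v, p):
    return Particle(
        position=np.array(x, dtype=np.int8),
        velocity=np.array(v, dtype=float),
        pbest_position=np.array(p, dtype=np.int8),
    )


def test_update_velocity_inertia_only():
    config = GPSOConfig(w=1.0, c1=0.0, c2=0.0)
    part = _particle([0, 1], [0.5, -0.5], [1, 1])
    v = update_velocity(part, np.array([1, 0]), config, np.random.default_rng(0))
    assert np.allclose(v, [0.5, -0.5])


def test_update_velocity_zero_attraction_at_consensus():
    config = GPSOConfig(w=0.7)
    part = _particle([1, 0], [1.0, -2.0], [1, 0])
    v = update_velocity(part, np.array([1, 0]), config, np.random.default_rng(0))
    assert np.allclose(v, [0.7, -1.4])


def test_update_velocity_hand_arithmetic():
    """w=0.5, v=1, c1=c2=1, r1=r2=0.5, (p-x)=2, (g-x)=4 -> v'=3.5."""

    class HalfRng:
        def random(self):
            return 0.5

    config = GPSOConfig(w=0.5, c1=1.0, c2=1.0, v_max=10.0)
    part = Particle(
        position=np.array([-1.0]),  # continuous scalar case
        velocity=np.array([1.0]),
        pbest_position=np.array([1.0]),
    )
    v = update_velocity(part, np.array([3.0]), config, HalfRng())
    assert v[0] == pytest.approx(3.5)


def test_update_velocity_clamped():
    config = GPSOConfig(w=1.0, c1=10.0, c2=10.0, v_max=2.0)
    part = _particle([0, 0], [2.0, 2.0], [1, 1])
    v = update_velocity(part, np.array([1, 1]), config, np.random.default_rng(0))
    assert np.all(np.abs(v) <= 2.0)


def test_update_position_saturation_and_determinism():
    config = GPSOConfig()
    part = _particle([0, 0, 0], [50.0, 50.0, 50.0], [0, 0, 0])
    bits = update_position(part, config, np.random.default_rng(0))
    assert bits.tolist() == [1, 1, 1]  # sigmoid(50) ~ 1
    part2 = _particle([0, 0, 0], [0.0, 0.0, 0.0], [0, 0, 0])
    a = update_position(part2, config, np.random.default_rng(9))
    b = update_position(part2, config, np.random.default_rng(9))
    assert np.array_equal(a, b)


def test_update_position_repairs_all_zero_with_max_velocity_bit():
    config = GPSOConfig()
    part = _particle([1, 1], [-60.0, -50.0], [1, 1])
    bits = update_position(part, config, np.random.default_rng(0))
    assert bits.tolist() == [0, 1]  # largest (least negative) velocity bit set


@pytest.mark.parametrize(
    "lam, acc, size, total, expected",
    [
        (1.0, 0.73, 5, 100, 0.73),
        (0.5, 0.8, 20, 100, 0.3),
        (0.0, 1.0, 100, 100, -1.0),
    ],
)
def test_out_group_fitness_arithmetic(lam, acc, size, total, expected):
    assert out_group_fitness(acc, size, total, lam) == pytest.approx(expected)


def test_out_group_fitness_validation():
    with pytest.raises(ValueError):
        out_group_fitness(0.5, 1, 0, 0.9)
    with pytest.raises(ValueError):
        out_group_fitness(0.5, 0, 10, 0.9)


def test_in_group_fitness_is_accuracy(separable_dataset, fast_protocol):
    dataset, roles = separable_dataset
    pool = np.arange(dataset.n_features)
    position = np.zeros(dataset.n_features, dtype=np.int8)
    position[np.flatnonzero(roles == "informative")] = 1
    record = in_group_fitness(position, pool, dataset, fast_protocol)
    assert record.in_fitness == record.acc
    assert record.acc >= 0.95  # separable by construction
    with pytest.raises(ValueError):
        in_group_fitness(np.zeros(5, dtype=np.int8), pool[:5], dataset, fast_protocol)


def test_in_group_fitness_null_on_permuted_labels(separable_dataset, fast_protocol):
    """Label-permuted data scores near the majority-class rate (binomial null)."""
    import iggpso

    dataset, _ = separable_dataset
    rng = np.random.default_rng(0)
    shuffled = iggpso.ExpressionDataset(
        expression=dataset.expression,
        labels=rng.permutation(dataset.labels),
        feature_ids=dataset.feature_ids,
        sample_ids=dataset.sample_ids,
    )
    pool = np.arange(20)
    position = np.ones(20, dtype=np.int8)
    record = in_group_fitness(position, pool, shuffled, fast_protocol)
    counts = np.bincount(shuffled.labels)
    p0 = counts.max() / counts.sum()
    sd = np.sqrt(p0 * (1 - p0) / shuffled.n_samples)
    assert abs(record.acc - p0) <= 3 * sd + 0.05


def _two_group_setup(separable_dataset):
    dataset, roles = separable_dataset
    import iggpso

    ranked = iggpso.rank_features(dataset)
    return dataset, roles, partition_features(ranked, 3)


def test_run_gpso_deterministic(separable_dataset, fast_protocol):
    dataset, _, groups = _two_group_setup(separable_dataset)
    config = GPSOConfig(seed=7, max_iter=5, patience=3, swarm_size=6)
    a = run_gpso(groups, dataset, config, fast_protocol)
    b = run_gpso(groups, dataset, config, fast_protocol)
    assert a.selected.tolist() == b.selected.tolist()
    assert a.acc == b.acc
    assert a.history == b.history


def test_run_gpso_finds_planted_signal(separable_dataset, fast_protocol):
    dataset, roles, groups = _two_group_setup(separable_dataset)
    config = GPSOConfig(seed=3, max_iter=15, patience=5, swarm_size=10)
    result = run_gpso(groups, dataset, config, fast_protocol)
    assert result.fs == len(result.selected) >= 1
    assert result.acc >= 0.95
    # planted features dominate the selection
    planted = np.mean(roles[result.selected] != "irrelevant")
    assert planted >= 0.5


def test_run_gpso_gbest_monotone_within_phase(separable_dataset, fast_protocol):
    dataset, _, groups = _two_group_setup(separable_dataset)
    config = GPSOConfig(seed=1, max_iter=8, patience=4, swarm_size=6)
    result = run_gpso(groups, dataset, config, fast_protocol)
    by_phase = {}
    for row in result.history:
        if "gbest_in_fitness" in row:
            by_phase.setdefault(row["phase"], []).append(row["gbest_in_fitness"])
    for series in by_phase.values():
        assert all(b >= a for a, b in zip(series, series[1:]))


def test_run_gpso_cache_transparent(separable_dataset, fast_protocol):
    dataset, _, groups = _two_group_setup(separable_dataset)
    base = dict(seed=5, max_iter=4, patience=2, swarm_size=5)
    with_cache = run_gpso(groups, dataset, GPSOConfig(**base), fast_protocol)
    without = run_gpso(
        groups, dataset, GPSOConfig(**base, use_cache=False), fast_protocol
    )
    assert with_cache.selected.tolist() == without.selected.tolist()
    assert with_cache.acc == without.acc


def test_single_group_reduces_to_plain_pso(separable_dataset, fast_protocol):
    """k=1 grouped search is bit-for-bit a plain binary PSO run."""
    dataset, _, _ = separable_dataset[0], None, None
    config = GPSOConfig(seed=11, max_iter=6, patience=3, swarm_size=6, lambda_=1.0)
    plain = pso_select(dataset, config, fast_protocol)
    single = FeatureGroups(
        groups=[np.arange(dataset.n_features, dtype=np.int64)], i_index=0.0
    )
    grouped = run_gpso(single, dataset, config, fast_protocol)
    assert plain.selected.tolist() == grouped.selected.tolist()
    assert plain.history == grouped.history
    assert plain.acc == grouped.acc


def test_run_gpso_rejects_empty_groups(separable_dataset, fast_protocol):
    with pytest.raises(ValueError):
        FeatureGroups(groups=[], i_index=0.0)
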