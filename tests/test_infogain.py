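"""Entropy estimators against hand values and a brute-force contingency oracle."""

import numpy as np
import pytest

from iggpso import (
    DiscretizationScheme,
    ExpressionDataset,
    class_entropy,
    conditional_entropy,
    information_gain,
    joint_entropy,
    rank_features,
)


def oracle_entropies(table):
    """Brute-force sums over an explicit bins x classes contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    h_class = 0.0
    for pj in table.sum(axis=0) / total:
        if pj > 0:
            h_class -= pj * np.log2(pj)
    h_cond = 0.0
    h_joint = 0.0
    for i in range(table.shape[0]):
        row_total = table[i].sum()
        for j in range(table.shape[1]):
            p_ij = table[i, j] / total
            if p_ij > 0:
                h_joint -= p_ij * np.log2(p_ij)
                h_cond -= p_ij * np.log2(table[i, j] / row_total)
    return h_class, h_cond, h_joint


def expand(table):
    """Turn a contingency table into (bin codes, class codes) vectors."""
    bins, classes = [], []
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            bins.extend([i] * int(table[i, j]))
            classes.extend([j] * int(table[i, j]))
    return np.array(bins), np.array(classes)


@pytest.mark.parametrize(
    "labels, expected",
    [
        (list("aabb"), 1.0),
        (list("aaa"), 0.0),
        (list("a" + "b" * 3), 0.811278),  # proportions (0.25, 0.75)
    ],
)
def test_class_entropy_hand_values(labels, expected):
    assert class_entropy(np.array(labels)) == pytest.approx(expected, abs=1e-6)


def test_class_entropy_rejects_empty():
    with pytest.raises(ValueError):
        class_entropy(np.array([]))


def test_conditional_entropy_perfect_predictor_and_independence():
    y = np.array([0, 0, 1, 1])
    assert conditional_entropy(y, y) == 0.0
    assert conditional_entropy(np.zeros(4), y) == pytest.approx(class_entropy(y))


def test_conditional_entropy_length_mismatch():
    with pytest.raises(ValueError):
        conditional_entropy(np.array([0, 1]), np.array([0, 1, 1]))


def test_counts_3113_table():
    """The 2x2 table [[3,1],[1,3]]: H(C|f)=0.811278, H(f,C)=1.811278, IG=0.188722."""
    table = np.array([[3, 1], [1, 3]])
    bins, classes = expand(table)
    assert conditional_entropy(bins, classes) == pytest.approx(0.811278, abs=1e-6)
    assert joint_entropy(bins, classes) == pytest.approx(1.811278, abs=1e-6)
    scheme = DiscretizationScheme(n_bins=2)
    ig = information_gain(bins.astype(float), classes, scheme)
    assert ig == pytest.approx(1.0 - 0.811278, abs=1e-6)


def test_chain_rule_on_random_tables():
    """H(f,C) = H(C|f) + H(f) on random contingency tables (oracle-checked)."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        table = rng.integers(0, 8, size=(rng.integers(2, 6), rng.integers(2, 4)))
        if table.sum() == 0:
            continue
        bins, classes = expand(table)
        h_bins = class_entropy(bins)  # entropy of the bin marginal
        assert joint_entropy(bins, classes) == pytest.approx(
            conditional_entropy(bins, classes) + h_bins, abs=1e-9
        )


def test_entropies_match_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        table = rng.integers(0, 6, size=(rng.integers(2, 7), rng.integers(2, 5)))
        if table.sum() < 2:
            continue
        bins, classes = expand(table)
        h_class, h_cond, h_joint = oracle_entropies(table)
        assert class_entropy(classes) == pytest.approx(h_class, abs=1e-9)
        assert conditional_entropy(bins, classes) == pytest.approx(h_cond, abs=1e-9)
        assert joint_entropy(bins, classes) == pytest.approx(h_joint, abs=1e-9)


def test_information_gain_limits():
    y = np.array([0, 0, 1, 1])
    scheme = DiscretizationScheme(n_bins=2)
    # perfectly separating binary feature on balanced classes
    assert information_gain(np.array([0.0, 0.0, 1.0, 1.0]), y, scheme) == pytest.approx(1.0)
    # constant feature carries nothing
    assert information_gain(np.zeros(4), y, scheme) == 0.0


def test_information_gain_rejects_non_finite():
    with pytest.raises(ValueError):
        information_gain(np.array([0.0, np.nan]), np.array([0, 1]))


def test_ig_bounds_on_random_instances():
    """0 <= IG <= H(C) for random discrete features (the spec-level invariant)."""
    rng = np.random.default_rng(2)
    scheme = DiscretizationScheme(n_bins=6)
    for _ in range(200):
        n = rng.integers(4, 41)
        y = rng.integers(0, rng.integers(2, 5), size=n)
        if len(np.unique(y)) < 2:
            continue
        x = rng.integers(0, 6, size=n).astype(float)
        ig = information_gain(x, y, scheme)
        assert 0.0 <= ig <= class_entropy(y) + 1e-12


def test_ig_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    y = rng.integers(0, 3, size=30)
    perm = rng.permutation(30)
    assert information_gain(x, y) == pytest.approx(information_gain(x[perm], y[perm]), abs=1e-12)


def _dataset_from_matrix(matrix, labels):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        expression=matrix,
        labels=np.asarray(labels),
        feature_ids=[f"f{j}" for j in range(matrix.shape[1])],
        sample_ids=[f"s{i}" for i in range(matrix.shape[0])],
    )


def test_rank_features_stable_tie_break():
    """Equal-IG features keep ascending original index order."""
    y = np.array([0, 0, 1, 1])
    # f0 uninformative; f1 and f2 identical perfect separators (tied IG)
    matrix = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [1.0, 1.0, 1.0]]
    )
    ranked = rank_features(_dataset_from_matrix(matrix, y), DiscretizationScheme(n_bins=2))
    assert ranked.order.tolist() == [1, 2, 0]
    assert ranked.ig[0] == ranked.ig[1] == pytest.approx(1.0)


def test_rank_features_matches_sort_oracle():
    rng = np.random.default_rng(4)
    matrix = rng.normal(size=(40, 50))
    y = rng.integers(0, 2, size=40)
    scheme = DiscretizationScheme(n_bins=5)
    ds = _dataset_from_matrix(matrix, y)
    ranked = rank_features(ds, scheme)
    ig = np.array([information_gain(matrix[:, j], y, scheme) for j in range(50)])
    expected_order = sorted(range(50), key=lambda j: (-ig[j], j))
    assert ranked.order.tolist() == expected_order
    assert np.allclose(ranked.ig, ig[ranked.order])
    assert np.all(np.diff(ranked.ig) <= 1e-12)


def test_discretization_constant_feature_single_bin():
    scheme = DiscretizationScheme(n_bins=10)
    codes = scheme.apply(np.full(5, 3.7))
    assert np.all(codes == codes[0])


def test_discretization_rejects_bad_bins():
    with pytest.raises(ValueError):
        DiscretizationScheme(n_bins=1)
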