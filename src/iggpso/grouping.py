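"""Partition IG-ranked features into contiguous groups of ~equal total IG.

The group count is k = ceil(M / gamma) for M features and a target group
size gamma, and the information index is the per-group share of the total
IG, I_index = sum |IG(f_i)| / k.  A greedy sweep over the descending-ranked
features closes a group as soon as its cumulative IG reaches the index,
while guaranteeing that all k groups end up non-empty and that any
remainder joins the final group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .infogain import RankedFeatures

__all__ = ["FeatureGroups", "group_count", "information_index", "partition_features"]


@dataclass
class FeatureGroups:
    """k contiguous blocks of the ranked feature order.

    ``groups[g]`` lists original feature indices, still in descending-IG
    order; ``ig_of`` maps each feature index to its IG value so downstream
    consumers (selection reports) need not re-rank.
    """

    groups: list[np.ndarray]
    i_index: float
    ig_of: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=np.int64) for g in self.groups]
        if not self.groups:
            raise ValueError("at least one group required")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("every group must be non-empty")
        flat = np.concatenate(self.groups)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("groups must be pairwise disjoint")

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_features(self) -> int:
        return sum(len(g) for g in self.groups)

    def group_of(self, feature: int) -> int:
        for g, members in enumerate(self.groups):
            if feature in members:
                return g
        raise KeyError(feature)


def group_count(n_features: int, gamma: int) -> int:
    """k = ceil(n_features / gamma); clamped to [1, n_features]."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if gamma > n_features:
        warnings.warn(
            f"gamma={gamma} exceeds the number of features ({n_features}); using a single group",
            stacklevel=2,
        )
        return 1
    return min(math.ceil(n_features / gamma), n_features)


def information_index(ig_values: np.ndarray, k: int) -> float:
    """Target cumulative IG per group: sum |IG| / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.sum(np.abs(np.asarray(ig_values, dtype=float))) / k)


def partition_features(ranked: RankedFeatures, k: int) -> FeatureGroups:
    """Greedy sweep closing each group once its cumulative IG reaches I_index.

    The sweep walks the ranked order; a group also closes early when only
    exactly enough features remain to keep all later groups non-empty, and
    the final group absorbs any remainder.
    """
    n = len(ranked)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot form {k} non-empty groups from {n} features")
    target = information_index(ranked.ig, k)
    groups: list[list[int]] = []
    current: list[int] = []
    cum = 0.0
    for position, (feature, ig) in enumerate(zip(ranked.order, ranked.ig)):
        current.append(int(feature))
        cum += abs(float(ig))
        remaining_features = n - (position + 1)
        remaining_groups = k - len(groups) - 1
        if remaining_groups == 0:
            continue  # final group absorbs the remainder
        must_close = remaining_features == remaining_groups
        reached = cum >= target - 1e-12
        if must_close or reached:
            groups.append(current)
            current = []
            cum = 0.0
    groups.append(current)
    assert len(groups) == k
    return FeatureGroups(
        groups=[np.asarray(g, dtype=np.int64) for g in groups],
        i_index=target,
        ig_of={int(f): float(v) for f, v in zip(ranked.order, ranked.ig)},
    )
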