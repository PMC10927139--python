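"""Entropy-based feature scoring and ranking.

The information gain of a feature f with respect to the class variable C is

    IG(f) = H(C) - H(C | f)

with entropies in bits (log base 2) and probabilities estimated from sample
frequencies.  Continuous expression values are discretized by equal-width
binning before the conditional entropy is formed; a feature with zero range
collapses to a single bin and carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset

__all__ = [
    "DiscretizationScheme",
    "RankedFeatures",
    "discretize",
    "class_entropy",
    "conditional_entropy",
    "joint_entropy",
    "information_gain",
    "rank_features",
]

# empirical mutual information is non-negative; tolerate rounding this far below 0
_IG_TOL = 1e-12


@dataclass
class DiscretizationScheme:
    """Equal-width binning of a continuous feature into ``n_bins`` intervals."""

    method: str = "equal_width"
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.method != "equal_width":
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def edges(self, values: np.ndarray) -> np.ndarray:
        """Strictly increasing interior cut points (n_bins - 1 of them).

        A degenerate (constant) feature has no cut points: every sample
        falls into one bin.
        """
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi <= lo:
            return np.empty(0)
        return np.linspace(lo, hi, self.n_bins + 1)[1:-1]

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite for discretization")
        return np.searchsorted(self.edges(values), values, side="right")


def discretize(values: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Bin codes (0..n_bins-1) for a feature under the scheme."""
    return scheme.apply(values)


@dataclass
class RankedFeatures:
    """Feature indices sorted by descending IG with matching IG values."""

    order: np.ndarray
    ig: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.ig = np.asarray(self.ig, dtype=float)
        if self.order.shape != self.ig.shape:
            raise ValueError("order and ig must align")
        n = len(self.order)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of 0..n_features-1")
        if np.any(np.diff(self.ig) > 1e-12):
            raise ValueError("ig values must be non-increasing along the ranking")
        if np.any(self.ig < -_IG_TOL):
            raise ValueError("information gain cannot be negative")

    def __len__(self) -> int:
        return len(self.order)


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float).ravel()
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _contingency(feature_bins: np.ndarray, labels: np.ndarray) -> np.ndarray:
    feature_bins = np.asarray(feature_bins)
    labels = np.asarray(labels)
    if feature_bins.shape != labels.shape:
        raise ValueError(
            f"feature_bins ({len(feature_bins)}) and labels ({len(labels)}) differ in length"
        )
    if len(labels) == 0:
        raise ValueError("empty input")
    _, bi = np.unique(feature_bins, return_inverse=True)
    _, ci = np.unique(labels, return_inverse=True)
    table = np.zeros((bi.max() + 1, ci.max() + 1))
    np.add.at(table, (bi, ci), 1.0)
    return table


def class_entropy(labels: np.ndarray) -> float:
    """H(C) in bits from empirical class frequencies."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute entropy of an empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts)


def conditional_entropy(feature_bins: np.ndarray, labels: np.ndarray) -> float:
    """H(C | f) in bits: bin-weighted entropy of the labels within each bin."""
    table = _contingency(feature_bins, labels)
    total = table.sum()
    h = 0.0
    for row in table:  # one feature bin per row
        weight = row.sum() / total
        if weight > 0:
            h += weight * _entropy_from_counts(row)
    return float(h)


def joint_entropy(feature_bins: np.ndarray, labels: np.ndarray) -> float:
    """H(f, C) in bits over the joint (bin, class) cells."""
    table = _contingency(feature_bins, labels)
    return _entropy_from_counts(table)


def information_gain(
    feature_values: np.ndarray,
    labels: np.ndarray,
    scheme: DiscretizationScheme | None = None,
) -> float:
    """IG(f) = H(C) - H(C | binned f), clipped to 0 against rounding."""
    if scheme is None:
        scheme = DiscretizationScheme()
    feature_values = np.asarray(feature_values, dtype=float)
    if not np.all(np.isfinite(feature_values)):
        raise ValueError("feature values must be finite")
    bins = scheme.apply(feature_values)
    ig = class_entropy(labels) - conditional_entropy(bins, labels)
    if ig < -_IG_TOL:
        raise AssertionError(f"information gain {ig} below rounding tolerance")
    return max(ig, 0.0)


def rank_features(
    dataset: ExpressionDataset, scheme: DiscretizationScheme | None = None
) -> RankedFeatures:
    """IG of every feature, sorted descending; ties broken by ascending index."""
    if scheme is None:
        scheme = DiscretizationScheme()
    dataset.validate_supervised()
    labels = dataset.labels
    h_class = class_entropy(labels)
    ig = np.empty(dataset.n_features)
    for j in range(dataset.n_features):
        bins = scheme.apply(dataset.expression[:, j])
        ig[j] = max(h_class - conditional_entropy(bins, labels), 0.0)
    # stable sort on -ig keeps ties in ascending original-index order
    order = np.argsort(-ig, kind="stable")
    return RankedFeatures(
        order=order,
        ig=ig[order],
        feature_ids=[dataset.feature_ids[j] for j in order],
    )
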