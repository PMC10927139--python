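"""Subset evaluation (cross-validated accuracy) and baseline selectors.

The evaluation protocol is stratified k-fold cross-validation with features
standardized to zero mean / unit variance using training-fold statistics
only, scored by plain accuracy (ACC).  The feature scale (FS) of a selector
is simply the size of the subset it returns.

Baselines mirror the standard filter / wrapper / hybrid taxonomy:

* filters score each feature independently (information gain, chi-square of
  the binned-feature x class contingency table, or absolute Pearson
  correlation with the class) and keep the top half of the informative
  (score > 0) features;
* the wrapper is a plain binary PSO over all features;
* hybrids run a filter first and the PSO wrapper on the survivors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .dataio import ExpressionDataset
from .friedman import HIGHER, LOWER, RankTable
from .infogain import DiscretizationScheme, information_gain

__all__ = [
    "EvalProtocol",
    "evaluate_subset",
    "feature_scores",
    "filter_select",
    "pso_select",
    "hybrid_select",
    "benchmark",
]


@dataclass
class EvalProtocol:
    """How candidate subsets are scored: classifier + CV layout."""

    classifier: str = "svm"
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    knn_k: int = 5
    cv_folds: int = 5
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "knn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def make_classifier(self):
        if self.classifier == "svm":
            return SVC(kernel=self.svm_kernel, C=self.svm_c)
        return KNeighborsClassifier(n_neighbors=self.knn_k)

    def fold_indices(self, labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        _, counts = np.unique(labels, return_counts=True)
        if self.cv_folds > counts.min():
            raise ValueError(
                f"cv_folds={self.cv_folds} exceeds the smallest class count ({counts.min()}); "
                "stratification infeasible"
            )
        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.cv_seed
        )
        return list(skf.split(np.zeros(len(labels)), labels))


def evaluate_subset(
    dataset: ExpressionDataset,
    subset: np.ndarray,
    protocol: EvalProtocol,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Stratified cross-validated accuracy of the protocol's classifier on a subset.

    ``folds`` lets callers (the swarm inner loop) reuse precomputed fold
    indices; when omitted they are derived from the protocol's ``cv_seed``,
    so repeated calls are deterministic.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("cannot evaluate an empty feature subset")
    if subset.min() < 0 or subset.max() >= dataset.n_features:
        raise IndexError("subset indices out of range")
    x = dataset.expression[:, subset]
    y = dataset.labels
    if folds is None:
        folds = protocol.fold_indices(y)
    correct = 0
    total = 0
    for train_idx, test_idx in folds:
        x_train, x_test = x[train_idx], x[test_idx]
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0  # constant-in-fold features carry no scale
        clf = protocol.make_classifier()
        clf.fit((x_train - mu) / sd, y[train_idx])
        pred = clf.predict((x_test - mu) / sd)
        correct += int(np.sum(pred == y[test_idx]))
        total += len(test_idx)
    return correct / total


def _chi2_statistic(table: np.ndarray) -> float:
    """Pearson chi-square sum((O-E)^2/E) over non-empty rows/columns."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(np.sum((table - expected) ** 2 / expected))


def _pearson_score(values: np.ndarray, labels: np.ndarray) -> float:
    """|r| against the class; multi-class as max over one-vs-rest encodings."""
    if np.std(values) == 0:
        return 0.0
    classes = np.unique(labels)
    if len(classes) == 2:
        encodings = [(labels == classes[1]).astype(float)]
    else:
        encodings = [(labels == c).astype(float) for c in classes]
    best = 0.0
    for y in encodings:
        if np.std(y) == 0:
            continue
        r = abs(float(np.corrcoef(values, y)[0, 1]))
        best = max(best, r)
    return best


def feature_scores(
    dataset: ExpressionDataset,
    method: str,
    scheme: DiscretizationScheme | None = None,
) -> np.ndarray:
    """Per-feature relevance scores: ``ig``, ``chi2`` or ``pearson``."""
    if scheme is None:
        scheme = DiscretizationScheme()
    dataset.validate_supervised()
    y = dataset.labels
    scores = np.empty(dataset.n_features)
    if method == "ig":
        for j in range(dataset.n_features):
            scores[j] = information_gain(dataset.expression[:, j], y, scheme)
    elif method == "chi2":
        from .infogain import _contingency

        for j in range(dataset.n_features):
            bins = scheme.apply(dataset.expression[:, j])
            scores[j] = _chi2_statistic(_contingency(bins, y))
    elif method == "pearson":
        for j in range(dataset.n_features):
            scores[j] = _pearson_score(dataset.expression[:, j], y)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    if not np.all(np.isfinite(scores)) or np.any(scores < 0):
        raise AssertionError("feature scores must be finite and non-negative")
    return scores


def filter_select(
    dataset: ExpressionDataset,
    method: str,
    scheme: DiscretizationScheme | None = None,
) -> np.ndarray:
    """Top half (by score) of the informative (score > 0) features.

    The cut is ceil(n_informative / 2); score ties are broken by ascending
    feature index for reproducibility.
    """
    scores = feature_scores(dataset, method, scheme)
    informative = np.flatnonzero(scores > 0)
    if informative.size == 0:
        raise ValueError(f"no informative features under method {method!r}")
    keep = math.ceil(informative.size / 2)
    # stable sort on -score keeps ties in ascending index order
    ranked = informative[np.argsort(-scores[informative], kind="stable")]
    return np.sort(ranked[:keep])


def pso_select(dataset: ExpressionDataset, config, protocol: EvalProtocol):
    """Plain binary PSO wrapper over all features (single all-features group)."""
    from .gpso import run_gpso
    from .grouping import FeatureGroups

    groups = FeatureGroups(
        groups=[np.arange(dataset.n_features, dtype=np.int64)],
        i_index=0.0,
    )
    return run_gpso(groups, dataset, config, protocol)


def hybrid_select(
    dataset: ExpressionDataset,
    filter_method: str,
    scheme: DiscretizationScheme | None,
    config,
    protocol: EvalProtocol,
):
    """Filter stage then PSO wrapper restricted to the surviving features."""
    from .gpso import run_gpso
    from .grouping import FeatureGroups

    survivors = filter_select(dataset, filter_method, scheme)
    groups = FeatureGroups(groups=[survivors], i_index=0.0)
    return run_gpso(groups, dataset, config, protocol)


def benchmark(
    datasets: dict[str, ExpressionDataset],
    algorithms: dict[str, "callable"],
    protocols: dict[str, EvalProtocol],
) -> tuple[RankTable, RankTable]:
    """Score every selector on every dataset under every protocol.

    ``algorithms`` maps a name to ``fn(dataset, protocol) -> feature index
    array or SelectionResult``.  Returns an (ACC %, FS) pair of score
    tables with one row per dataset per protocol plus a trailing Average
    row per protocol (mean of finite cells; failed cells warn and are
    excluded).
    """
    if not datasets or not algorithms or not protocols:
        raise ValueError("need at least one dataset, one algorithm and one protocol")
    alg_names = list(algorithms)
    acc_rows, fs_rows, row_labels = [], [], []
    for proto_name, protocol in protocols.items():
        block_acc, block_fs = [], []
        for ds_name, dataset in datasets.items():
            acc_row = np.full(len(alg_names), np.nan)
            fs_row = np.full(len(alg_names), np.nan)
            for a, alg_name in enumerate(alg_names):
                try:
                    out = algorithms[alg_name](dataset, protocol)
                    subset = np.asarray(getattr(out, "selected", out), dtype=np.int64)
                    acc_row[a] = 100.0 * evaluate_subset(dataset, subset, protocol)
                    fs_row[a] = subset.size
                except Exception as exc:  # failed cell: record missing, keep going
                    warnings.warn(
                        f"{alg_name} failed on {ds_name} [{proto_name}]: {exc}",
                        stacklevel=2,
                    )
            block_acc.append(acc_row)
            block_fs.append(fs_row)
            row_labels.append(f"{ds_name}[{proto_name}]")
        acc_rows.extend(block_acc)
        fs_rows.extend(block_fs)
        with warnings.catch_warnings():
            # a column with every cell failed averages to NaN, silently
            warnings.simplefilter("ignore", RuntimeWarning)
            acc_rows.append(np.nanmean(np.array(block_acc), axis=0))
            fs_rows.append(np.nanmean(np.array(block_fs), axis=0))
        row_labels.append(f"Average[{proto_name}]")
    n = len(row_labels)
    acc_table = RankTable(
        values=np.array(acc_rows),
        row_direction=[HIGHER] * n,
        row_labels=list(row_labels),
        column_labels=alg_names,
    )
    fs_table = RankTable(
        values=np.array(fs_rows),
        row_direction=[LOWER] * n,
        row_labels=list(row_labels),
        column_labels=alg_names,
    )
    return acc_table, fs_table
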