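"""Delimited-text I/O for expression matrices, score tables and results.

Expression data is kept samples-in-rows, features-in-columns.  The public
gene-expression benchmarks this package targets are often distributed
features-in-rows; pass ``transpose=True`` to flip on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .friedman import HIGHER, LOWER, RankTable

__all__ = [
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "write_selection",
    "read_selection",
    "read_score_table",
    "write_score_table",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless round trip at this precision


@dataclass
class ExpressionDataset:
    """A samples x features expression matrix with one class label per sample.

    ``labels`` holds contiguous integer class codes (0..m-1) assigned in
    first-appearance order of the original label values, which are kept in
    ``class_names`` so files round-trip with their original labels.
    """

    expression: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D matrix (samples x features)")
        n, p = self.expression.shape
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError(
                f"{len(self.labels)} labels for {n} samples; one label per matrix row required"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            # map arbitrary label values to stable first-appearance codes
            codes, names = _encode_labels(self.labels)
            self.labels = codes
            if not self.class_names:
                self.class_names = names
        if not self.class_names:
            self.class_names = [str(c) for c in range(int(self.labels.max()) + 1)]
        if len(self.feature_ids) != p:
            raise ValueError("one feature_id per column required")
        if len(self.sample_ids) != n:
            raise ValueError("one sample_id per row required")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be pairwise distinct")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be pairwise distinct")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def validate_supervised(self) -> None:
        """Reject datasets unusable for supervised selection (single class)."""
        if self.n_classes < 2:
            raise ValueError("supervised operations need at least 2 classes")


def _encode_labels(raw: Sequence) -> tuple[np.ndarray, list[str]]:
    names: list[str] = []
    index: dict = {}
    codes = np.empty(len(raw), dtype=np.int64)
    for i, value in enumerate(raw):
        key = value
        if key not in index:
            index[key] = len(names)
            names.append(str(value))
        codes[i] = index[key]
    return codes, names


def read_dataset(
    path: str | Path,
    label_column: str = "last",
    delimiter: str = ",",
    transpose: bool = False,
    impute: str | None = None,
) -> ExpressionDataset:
    """Load an expression table with a header row and a label column.

    Parameters
    ----------
    label_column:
        Name of the label column, or the sentinel ``"last"`` for the final
        column.  Ignored when ``transpose=True`` is combined with a label
        row is not supported; transpose applies to the feature block only.
    impute:
        ``None`` rejects missing values; ``"feature_mean"`` fills each
        feature's missing entries with its mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if label_column == "last":
        label_column = frame.columns[-1]
    if label_column not in frame.columns:
        raise KeyError(f"label column {label_column!r} not found in {path}")
    labels_raw = frame[label_column]
    feature_frame = frame.drop(columns=[label_column])
    if transpose:
        feature_frame = feature_frame.T
    matrix = np.empty(feature_frame.shape, dtype=float)
    for j, col in enumerate(feature_frame.columns):
        converted = pd.to_numeric(feature_frame[col], errors="coerce")
        bad = converted.isna() & feature_frame[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric expression value at row {row!r}, column {col!r} in {path}"
            )
        matrix[:, j] = converted.to_numpy()
    if np.isnan(matrix).any():
        if impute == "feature_mean":
            col_means = np.nanmean(matrix, axis=0)
            holes = np.where(np.isnan(matrix))
            matrix[holes] = col_means[holes[1]]
        else:
            raise ValueError(
                f"{path} contains missing expression values; pass impute='feature_mean' to fill"
            )
    dataset = ExpressionDataset(
        expression=matrix,
        labels=labels_raw.to_numpy(),
        feature_ids=[str(c) for c in feature_frame.columns],
        sample_ids=[str(i) for i in feature_frame.index],
    )
    dataset.validate_supervised()
    return dataset


def write_dataset(dataset: ExpressionDataset, path: str | Path, delimiter: str = ",") -> None:
    frame = pd.DataFrame(
        dataset.expression, index=dataset.sample_ids, columns=dataset.feature_ids
    )
    frame["label"] = [dataset.class_names[c] for c in dataset.labels]
    frame.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT, index_label="sample_id")


def write_selection(result, path: str | Path) -> None:
    """Write a selection result as CSV with a ``# key=value`` metadata block.

    Columns: ``feature_id,ig_value,group_index`` (one row per selected
    feature).  An empty selection produces a header-only file and a warning.
    """
    path = Path(path)
    meta = {
        "seed": result.seed,
        "config_hash": result.config_hash(),
        "acc": f"{result.acc:.6f}",
        "fs": result.fs,
    }
    rows = result.selection_rows()
    if not rows:
        log.warning("writing empty selection to %s", path)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write("feature_id,ig_value,group_index\n")
        for feature_id, ig, group in rows:
            fh.write(f"{feature_id},{_FLOAT_FMT % ig},{group}\n")


def read_selection(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back a selection CSV; returns (rows, metadata dict)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            body_start += 1
        else:
            break
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[body_start:])))
    return frame, meta


def read_score_table(path: str | Path, delimiter: str = ",") -> RankTable:
    """Read an algorithm x dataset score table.

    Expected layout: header row; first column dataset names, second column a
    per-row direction flag (``higher_better`` / ``lower_better``), remaining
    columns algorithm scores.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 4:
        raise ValueError(
            f"{path}: need dataset, direction and >=2 algorithm columns, got {frame.shape[1]}"
        )
    direction_col = frame.columns[1]
    directions = [str(d) for d in frame[direction_col]]
    bad = set(directions) - {HIGHER, LOWER}
    if bad:
        raise ValueError(
            f"{path}: column {direction_col!r} must hold direction flags "
            f"({HIGHER}/{LOWER}); found {sorted(bad)}"
        )
    values = frame.iloc[:, 2:].to_numpy(dtype=float)
    return RankTable(
        values=values,
        row_direction=directions,
        row_labels=[f"{d}:{m}" for d, m in zip(frame.iloc[:, 0], directions)],
        column_labels=[str(c) for c in frame.columns[2:]],
    )


def write_score_table(table: RankTable, path: str | Path, delimiter: str = ",") -> None:
    dataset_names = [lbl.rsplit(":", 1)[0] for lbl in table.row_labels]
    frame = pd.DataFrame(table.values, columns=table.column_labels)
    frame.insert(0, "direction", table.row_direction)
    frame.insert(0, "dataset", dataset_names)
    frame.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)
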