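"""Friedman multiple-comparison test over algorithm x dataset score tables.

The omnibus question: do k feature-selection algorithms, each scored on N
dataset/metric rows, differ systematically?  Each row is ranked on its own
(rank 1 = best, with the row's direction deciding whether larger or smaller
scores are better; ties share the average of the ranks they span), the
per-algorithm mean ranks R_j are formed, and the classical Friedman
chi-square

    chi2_F = 12 N / (k (k+1)) * (sum_j R_j^2 - k (k+1)^2 / 4)

is refined into the F-distributed form

    F_F = (N - 1) chi2_F / (N (k - 1) - chi2_F)

with (k-1, (N-1)(k-1)) degrees of freedom, compared against the upper-alpha
F quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RankTable",
    "FriedmanResult",
    "rank_rows",
    "friedman_chi2",
    "friedman_f",
    "f_critical",
    "friedman_test",
]

HIGHER = "higher_better"
LOWER = "lower_better"


@dataclass
class RankTable:
    """An N x k table of algorithm scores with a per-row ranking direction.

    Rows are dataset/metric combinations (e.g. accuracy on one dataset, or
    subset size on one dataset), columns are algorithms.  ``row_direction``
    says, per row, whether larger (``"higher_better"``, e.g. accuracy) or
    smaller (``"lower_better"``, e.g. feature count) scores are preferred.
    """

    values: np.ndarray
    row_direction: list[str]
    row_labels: list[str] = field(default_factory=list)
    column_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score table must be two-dimensional")
        n, k = self.values.shape
        if n < 1 or k < 2:
            raise ValueError(f"score table needs >=1 row and >=2 columns, got {n}x{k}")
        if len(self.row_direction) != n:
            raise ValueError("one direction flag required per row")
        bad = set(self.row_direction) - {HIGHER, LOWER}
        if bad:
            raise ValueError(f"unknown direction flag(s): {sorted(bad)}")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(n)]
        if not self.column_labels:
            self.column_labels = [f"alg{j}" for j in range(k)]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_algorithms(self) -> int:
        return self.values.shape[1]


@dataclass
class FriedmanResult:
    ranks: np.ndarray
    mean_ranks: np.ndarray
    chi2: float
    f_stat: float
    df1: int
    df2: int
    alpha: float
    critical_value: float
    reject: bool

    def report(self) -> str:
        """One-page plain-text summary of the test."""
        lines = [
            "Friedman multiple-comparison test",
            "=================================",
            f"rows (dataset/metric combinations) N = {self.ranks.shape[0]}",
            f"algorithms compared              k = {self.ranks.shape[1]}",
            f"chi-square statistic          chi2 = {self.chi2:.4f}",
            f"F-form statistic               F_F = {self.f_stat:.4f}",
            f"degrees of freedom                  ({self.df1}, {self.df2})",
            f"critical value F({self.alpha:g}; {self.df1}, {self.df2}) = {self.critical_value:.4f}",
            "decision: "
            + (
                "reject the null hypothesis - the algorithms differ significantly"
                if self.reject
                else "fail to reject the null hypothesis"
            ),
        ]
        return "\n".join(lines)


def rank_rows(table: RankTable) -> np.ndarray:
    """Within-row average ranks, rank 1 = best under the row's direction."""
    if not np.all(np.isfinite(table.values)):
        raise ValueError("score table contains non-finite values")
    ranks = np.empty_like(table.values)
    for i, direction in enumerate(table.row_direction):
        row = table.values[i]
        # rankdata ranks ascending; negate higher-better rows so the best
        # score receives rank 1
        ranks[i] = stats.rankdata(-row if direction == HIGHER else row)
    return ranks


def _validate_ranks(ranks: np.ndarray) -> tuple[int, int]:
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 2:
        raise ValueError("ranks must be a 2-D array")
    n, k = ranks.shape
    expected = k * (k + 1) / 2
    if not np.allclose(ranks.sum(axis=1), expected, atol=1e-8):
        raise ValueError(f"each rank row must sum to k(k+1)/2 = {expected}")
    return n, k


def friedman_chi2(ranks: np.ndarray, tie_correction: bool = False) -> float:
    """Friedman chi-square from an N x k matrix of within-row ranks.

    ``tie_correction`` divides the classical statistic by the standard tie
    factor 1 - sum(t^3 - t) / (N k (k^2 - 1)); the default leaves the
    statistic in its classical (uncorrected) form.
    """
    ranks = np.asarray(ranks, dtype=float)
    n, k = _validate_ranks(ranks)
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * (np.sum(mean_ranks**2) - k * (k + 1) ** 2 / 4.0)
    if tie_correction:
        t_sum = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            t_sum += float(np.sum(counts.astype(float) ** 3 - counts))
        denom = 1.0 - t_sum / (n * k * (k**2 - 1))
        if denom <= 0:
            raise ValueError("tie correction degenerate: every row fully tied")
        chi2 /= denom
    return float(chi2)


def friedman_f(chi2: float, n: int, k: int) -> float:
    """F-distributed refinement F_F = (N-1) chi2 / (N(k-1) - chi2)."""
    denom = n * (k - 1) - chi2
    if denom <= 0:
        raise ValueError(
            f"chi2={chi2} reaches its upper bound N(k-1)={n * (k - 1)}; "
            "the F-form statistic is undefined"
        )
    return float((n - 1) * chi2 / denom)


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha quantile of the F distribution with (df1, df2) dof."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def friedman_test(
    table: RankTable, alpha: float = 0.05, tie_correction: bool = False
) -> FriedmanResult:
    """Run the full test: rank rows, chi-square, F-form, critical value."""
    ranks = rank_rows(table)
    n, k = ranks.shape
    chi2 = friedman_chi2(ranks, tie_correction=tie_correction)
    f_stat = friedman_f(chi2, n, k)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    crit = f_critical(alpha, df1, df2)
    return FriedmanResult(
        ranks=ranks,
        mean_ranks=ranks.mean(axis=0),
        chi2=chi2,
        f_stat=f_stat,
        df1=df1,
        df2=df2,
        alpha=alpha,
        critical_value=crit,
        reject=bool(f_stat > crit),
    )
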