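"""Statistical tests and multiple-testing procedures shared by all stages.

Every p-value reported anywhere in the package is produced here, so the
conventions are fixed in one place:

* Pearson chi-square without continuity correction,
* Fisher's exact test with the minimum-likelihood two-sided convention,
* Wilcoxon rank-sum, exact for small untied samples and a tie-corrected
  normal approximation otherwise,
* Benjamini-Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

Sidedness = Literal["one_greater", "one_less", "two"]

_SCIPY_ALTERNATIVE = {
    "one_greater": "greater",
    "one_less": "less",
    "two": "two-sided",
}


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin (or zero grand total)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer counts with row/column labels.

    Rows are typically chromosome classes (X vs autosome) and columns
    expression-bias or presence categories.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError(
                f"contingency table must be at least 2x2, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        if counts.sum() == 0:
            raise DegenerateTableError("contingency table has zero grand total")
        object.__setattr__(self, "counts", counts)
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels", tuple(f"row{i}" for i in range(counts.shape[0]))
            )
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"col{j}" for j in range(counts.shape[1]))
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def check_margins(self) -> None:
        """Raise :class:`DegenerateTableError` naming any zero margin."""
        row_sums = self.counts.sum(axis=1)
        col_sums = self.counts.sum(axis=0)
        for i, s in enumerate(row_sums):
            if s == 0:
                raise DegenerateTableError(
                    f"row margin '{self.row_labels[i]}' is zero"
                )
        for j, s in enumerate(col_sums):
            if s == 0:
                raise DegenerateTableError(
                    f"column margin '{self.col_labels[j]}' is zero"
                )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    sided: Sidedness
    df: int | None = None
    method: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        # Clip tiny negative round-off; anything else is a real bug upstream.
        if -1e-12 <= self.p_value < 0.0:
            object.__setattr__(self, "p_value", 0.0)
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError(f"df must be >= 1 when defined, got {self.df}")


def chi_square_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    ``df = (r - 1)(c - 1)``; the p-value is the upper tail of the
    chi-square distribution. Zero row or column margins are rejected.
    """
    table.check_margins()
    res = _sps.chi2_contingency(table.counts, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sided="two",
        df=int(res.dof),
        method="chi_square_independence",
    )


def fisher_exact(table: ContingencyTable, sided: Sidedness = "two") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) whose hypergeometric probability does not exceed the observed
    one; one-sided p is the corresponding hypergeometric tail for the
    top-left cell. A table with any zero margin carries no information and
    returns p = 1.
    """
    if table.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got {table.shape}")
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        # no variation in one margin: only one table is possible
        odds = _odds_ratio(counts)
        return TestResult(statistic=odds, p_value=1.0, sided=sided,
                          method="fisher_exact")
    res = _sps.fisher_exact(counts, alternative=_SCIPY_ALTERNATIVE[sided])
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        sided=sided,
        method="fisher_exact",
    )


def _odds_ratio(counts: np.ndarray) -> float:
    a, b = counts[0]
    c, d = counts[1]
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return float(a * d) / float(b * c)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    sided: Sidedness = "two",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when ``min(n, m) <= 12`` and there are no ties
    between or within the samples; otherwise the tie-corrected normal
    approximation (no continuity correction). ``one_greater`` tests for
    a stochastically larger ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 12 and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(
        x, y,
        alternative=_SCIPY_ALTERNATIVE[sided],
        method=method,
        use_continuity=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        sided=sided,
        method=f"wilcoxon_rank_sum[{method}]",
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Adjusted value for the i-th smallest p is
    ``min over j >= i of (m * p_(j) / j)`` capped at 1; output is returned
    in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out
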