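"""Relative-abundance profiles, expression divergence, and the
exponential-decay model of male-bias proportion versus gene age.

Relative abundance (RA) of a gene in a tissue is its intensity there as a
fraction of its summed intensity across tissues; cross-species divergence
D between orthologs is the sum over tissues of squared RA differences
(0 <= D <= 2 for probability vectors; the square root is deliberately not
taken).

The decay model describes the proportion of male-biased genes among genes
that originated at age ``t`` (myr, t <= 0):

    f(t) = N * (exp(r * t) * (1 - d) + d)

``N`` is the proportion at the present (t = 0), ``r`` the decay rate per
myr, and ``N * d`` the deep-time plateau. It is fitted by weighted
nonlinear least squares (weights = per-branch gene counts, equivalent to
Gaussian maximum likelihood with variance inversely proportional to the
count) with box constraints and jittered multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stats import TestResult, wilcoxon_rank_sum


@dataclass(frozen=True)
class RAProfile:
    gene_id: str
    tissues: tuple[str, ...]
    ra: np.ndarray
    defined: bool = True  # False when total intensity was zero

    def __post_init__(self) -> None:
        ra = np.asarray(self.ra, dtype=float)
        object.__setattr__(self, "ra", ra)
        if len(self.tissues) != ra.size:
            raise ValueError("tissue axis and RA vector length differ")
        if self.defined and abs(ra.sum() - 1.0) > 1e-9:
            raise ValueError("defined RA profile must sum to 1")


@dataclass(frozen=True)
class DivergenceScore:
    gene_id: str
    D: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("divergence must be non-negative")


def relative_abundance(
    intensities: Sequence[float],
    tissues: Sequence[str],
    gene_id: str = "",
) -> RAProfile:
    """Component-wise intensity / total; all-zero input yields an
    undefined (flagged) profile."""
    values = np.asarray(intensities, dtype=float)
    if (values < 0).any():
        raise ValueError("intensities must be non-negative")
    total = values.sum()
    if total == 0:
        return RAProfile(gene_id, tuple(tissues), np.zeros_like(values), defined=False)
    return RAProfile(gene_id, tuple(tissues), values / total)


def expression_divergence(a: RAProfile, b: RAProfile) -> DivergenceScore:
    """D = sum over tissues of (RA_a - RA_b)^2, on a shared tissue axis."""
    if a.tissues != b.tissues:
        raise ValueError("RA profiles are on different tissue axes")
    if not (a.defined and b.defined):
        raise ValueError("cannot compare undefined RA profiles")
    diff = a.ra - b.ra
    return DivergenceScore(gene_id=a.gene_id, D=float(np.dot(diff, diff)))


def ra_table(
    intensities: pd.DataFrame, tissue_of: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """RA per gene across columns (averaging replicate columns per tissue
    first when ``tissue_of`` maps column -> tissue). Genes with zero total
    are dropped."""
    if tissue_of is not None:
        grouped = intensities.T.groupby(
            intensities.columns.map(tissue_of.__getitem__)
        ).mean().T
    else:
        grouped = intensities
    totals = grouped.sum(axis=1)
    kept = grouped.loc[totals > 0]
    return kept.div(kept.sum(axis=1), axis=0)


def divergence_table(ra_a: pd.DataFrame, ra_b: pd.DataFrame) -> pd.Series:
    """Per-gene D over the shared genes of two same-axis RA tables."""
    if list(ra_a.columns) != list(ra_b.columns):
        raise ValueError("RA tables are on different tissue axes")
    shared = ra_a.index.intersection(ra_b.index)
    diff = ra_a.loc[shared].to_numpy() - ra_b.loc[shared].to_numpy()
    return pd.Series((diff ** 2).sum(axis=1), index=shared, name="D")


def group_divergence_compare(
    scores: Mapping[str, Sequence[float]],
    sided: str = "two",
) -> pd.DataFrame:
    """Pairwise rank-sum tests across named groups of divergence scores.

    With ``one_greater`` the first group of each (alphabetical) pair is
    tested for stochastically larger divergence.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
    non_empty = {k: v for k, v in groups.items() if v.size > 0}
    if len(non_empty) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    rows = []
    for a, b in combinations(sorted(non_empty), 2):
        res: TestResult = wilcoxon_rank_sum(non_empty[a], non_empty[b], sided=sided)
        rows.append(
            {
                "group_a": a, "group_b": b,
                "n_a": non_empty[a].size, "n_b": non_empty[b].size,
                "statistic": res.statistic, "p_value": res.p_value,
                "sided": sided,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DecayModel:
    """Parameters of f(t) = N (e^{rt} (1 - d) + d), t <= 0 in myr."""

    N: float
    r: float
    d: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be > 0")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must lie in [0, 1]")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.N * (np.exp(self.r * t) * (1.0 - self.d) + self.d)

    @property
    def plateau(self) -> float:
        """Deep-time male-bias proportion, lim f(t) as t -> -inf."""
        return self.N * self.d


@dataclass(frozen=True)
class DecayFit:
    model: DecayModel
    objective: float  # weighted sum of squared residuals
    converged: bool
    n_starts: int


def _decay_f(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    n, r, d = params
    return n * (np.exp(r * t) * (1.0 - d) + d)


def fit_decay(
    ages: Sequence[float],
    proportions: Sequence[float],
    counts: Sequence[float] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> DecayFit:
    """Weighted NLS fit of the decay model with jittered multi-start.

    ``counts`` (default all-one) weight each branch point by its gene
    count. Initialisation: N0 = proportion at the youngest age, d0 =
    oldest/youngest proportion ratio clipped to [0.01, 0.99], r0 = 0.05,
    then ``n_starts - 1`` log-normal/normal jitters of that start.
    """
    t = np.asarray(ages, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if t.size != p.size:
        raise ValueError("ages and proportions differ in length")
    if t.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    if (t > 0).any():
        raise ValueError("ages must be <= 0 (myr before present)")
    w = np.ones_like(p) if counts is None else np.asarray(counts, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    sw = np.sqrt(w)

    def residuals(params: np.ndarray) -> np.ndarray:
        return sw * (p - _decay_f(params, t))

    order = np.argsort(t)
    p_young = max(p[order[-1]], 1e-6)
    p_old = max(p[order[0]], 1e-6)
    d0 = float(np.clip(p_old / p_young, 0.01, 0.99))
    base = np.array([p_young, 0.05, d0])
    lower = np.array([1e-9, 0.0, 0.0])
    upper = np.array([np.inf, np.inf, 1.0])
    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    for k in range(n_starts):
        start = base.copy()
        if k > 0:
            start[0] *= np.exp(rng.normal(0, 0.3))
            start[1] = abs(start[1] * np.exp(rng.normal(0, 1.0)))
            start[2] = float(np.clip(start[2] + rng.normal(0, 0.2), 0.01, 0.99))
        start = np.clip(start, lower + 1e-12, [1e6, 10.0, 1.0 - 1e-12])
        try:
            res = least_squares(residuals, start, bounds=(lower, upper))
        except Exception:
            continue
        if not res.success:
            continue
        n_converged += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("decay fit failed to converge from every start")
    n_hat, r_hat, d_hat = best.x
    model = DecayModel(N=float(n_hat), r=float(r_hat), d=float(min(d_hat, 1.0)))
    return DecayFit(
        model=model,
        objective=float(2.0 * best.cost),  # least_squares cost = 0.5 * SSR
        converged=n_converged > 0,
        n_starts=n_starts,
    )
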