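"""Expression presence/absence and testis-vs-ovary sex-bias calling.

Presence is a strict consensus over replicates: a gene is *present* only
if detected in every replicate, *absent* only if detected in none, and
*ambiguous* otherwise (ambiguous genes are excluded from downstream
proportions). Detection itself compares gene-level signal against a
background pool with a one-sided rank-sum test.

Sex bias is a gonad-vs-gonad comparison (testis vs ovary) on log2
intensities using a shrinkage t-statistic: per-gene variances are shrunk
toward the genome-wide mean variance with a prior weight expressed in
residual-degree-of-freedom units, which stabilises calls at the small
replicate numbers typical of microarray designs. p-values are BH-adjusted
across genes; "male-biased" means significantly higher in testis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_fdr, wilcoxon_rank_sum

PresenceState = Literal["present", "absent", "ambiguous"]
BiasState = Literal["male", "female", "unbiased", "not_assayed"]

#: prior weight (in residual-df units) pulling per-gene variances toward
#: the genome-wide mean; comparable to a moderately informative prior
DEFAULT_PRIOR_DF = 4.0


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample intensity matrix with a replicate-aware sample sheet.

    ``samples`` needs columns: sample, tissue, replicate_group, species
    (optional extras such as sex or cell_type pass through untouched).
    """

    intensities: pd.DataFrame  # genes x samples, linear units, >= 0
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "tissue", "replicate_group", "species"}
        if not required <= set(self.samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if list(self.intensities.columns) != list(self.samples["sample"]):
            raise ValueError("intensity columns must match sample sheet order")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample names")

    def columns_for(self, tissue: str) -> list[str]:
        mask = self.samples["tissue"] == tissue
        return list(self.samples.loc[mask, "sample"])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.intensities.index)


@dataclass(frozen=True)
class PresenceCall:
    gene_id: str
    tissue: str
    call: PresenceState


@dataclass(frozen=True)
class SexBiasCall:
    gene_id: str
    call: BiasState
    log2_fold_change: float = float("nan")  # testis minus ovary
    adjusted_p: float = float("nan")


def consensus_presence(
    flags: Sequence[bool], gene_id: str = "", tissue: str = ""
) -> PresenceCall:
    """All-replicates consensus: present/absent only when unanimous."""
    if len(flags) == 0:
        raise ValueError("need at least one replicate flag")
    if all(flags):
        call: PresenceState = "present"
    elif not any(flags):
        call = "absent"
    else:
        call = "ambiguous"
    return PresenceCall(gene_id=gene_id, tissue=tissue, call=call)


def expressed_proportion(calls: Iterable[PresenceCall]) -> float:
    """present / (present + absent); ambiguous calls are excluded.

    Returns NaN when no informative call remains.
    """
    n_present = n_absent = 0
    for c in calls:
        if c.call == "present":
            n_present += 1
        elif c.call == "absent":
            n_absent += 1
    if n_present + n_absent == 0:
        return float("nan")
    return n_present / (n_present + n_absent)


def detection_above_background(
    signal: Sequence[float], background: Sequence[float]
) -> float:
    """One-sided rank-sum p for gene signal exceeding the background pool."""
    return wilcoxon_rank_sum(signal, background, sided="one_greater").p_value


def detection_calls(
    matrix: ExpressionMatrix,
    background: Sequence[float],
    q_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Per-gene, per-replicate-group detection flags at a BH-adjusted cutoff.

    Returns a genes x replicate_group boolean frame. Probe-level signal is
    taken to be the replicate-group's columns for that gene.
    """
    groups = list(dict.fromkeys(matrix.samples["replicate_group"]))
    raw = np.empty((len(matrix.intensities), len(groups)), dtype=float)
    for j, grp in enumerate(groups):
        cols = list(
            matrix.samples.loc[matrix.samples["replicate_group"] == grp, "sample"]
        )
        sub = matrix.intensities[cols].to_numpy()
        for i in range(sub.shape[0]):
            raw[i, j] = detection_above_background(sub[i], background)
    adjusted = bh_fdr(raw.ravel()).reshape(raw.shape)
    return pd.DataFrame(
        adjusted < q_cutoff, index=matrix.intensities.index, columns=groups
    )


def shrinkage_t_test(
    group_a: np.ndarray, group_b: np.ndarray, prior_df: float = DEFAULT_PRIOR_DF
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t with variances shrunk toward the genome mean.

    Pooled per-gene variance ``s_g^2`` (df ``n_a + n_b - 2``) is replaced by
    ``(prior_df * mean(s^2) + df * s_g^2) / (prior_df + df)`` and the t
    statistic referred to ``df + prior_df`` degrees of freedom.

    Returns (t, p_two_sided, delta) where delta = mean(a) - mean(b).
    """
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    df = n_a + n_b - 2
    if df < 1:
        raise ValueError("need >= 2 total residual degrees of freedom")
    mean_a = group_a.mean(axis=1)
    mean_b = group_b.mean(axis=1)
    ss_a = ((group_a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((group_b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = (ss_a + ss_b) / df
    s2_shrunk = (prior_df * s2.mean() + df * s2) / (prior_df + df)
    se = np.sqrt(s2_shrunk * (1.0 / n_a + 1.0 / n_b))
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero residual variance: perfect separation unless the means agree
        t = np.divide(delta, se, out=np.zeros_like(delta), where=se > 0)
        t[(se == 0) & (delta != 0)] = np.inf * np.sign(delta[(se == 0) & (delta != 0)])
    p = 2.0 * _sps.t.sf(np.abs(t), df + prior_df)
    return t, p, delta


def call_sex_bias(
    matrix: ExpressionMatrix,
    testis_tissue: str = "testis",
    ovary_tissue: str = "ovary",
    fdr: float = 0.05,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> list[SexBiasCall]:
    """Testis-vs-ovary shrinkage t per gene, BH-adjusted across genes.

    ``male`` iff adjusted p < fdr with the testis mean higher; ``female``
    symmetric; fewer than 2 replicates in either gonad makes every gene
    ``not_assayed``.
    """
    t_cols = matrix.columns_for(testis_tissue)
    o_cols = matrix.columns_for(ovary_tissue)
    genes = matrix.gene_ids
    if len(t_cols) < 2 or len(o_cols) < 2:
        return [SexBiasCall(g, "not_assayed") for g in genes]
    log_t = np.log2(matrix.intensities[t_cols].to_numpy() + 1.0)
    log_o = np.log2(matrix.intensities[o_cols].to_numpy() + 1.0)
    _, p, delta = shrinkage_t_test(log_t, log_o, prior_df=prior_df)
    adj = bh_fdr(p)
    calls: list[SexBiasCall] = []
    for g, d, q in zip(genes, delta, adj):
        if q < fdr and d > 0:
            state: BiasState = "male"
        elif q < fdr and d < 0:
            state = "female"
        else:
            state = "unbiased"
        calls.append(SexBiasCall(g, state, log2_fold_change=float(d),
                                 adjusted_p=float(q)))
    return calls


def presence_calls_for_tissue(
    detection: pd.DataFrame, groups: Sequence[str], tissue: str
) -> list[PresenceCall]:
    """Consensus presence across the named replicate groups of one tissue."""
    missing = [g for g in groups if g not in detection.columns]
    if missing:
        raise KeyError(f"unknown replicate groups {missing}")
    sub = detection[list(groups)].to_numpy()
    return [
        consensus_presence(list(sub[i]), gene_id=str(g), tissue=tissue)
        for i, g in enumerate(detection.index)
    ]


# ---------------------------------------------------------------------------
# I/O


def read_expression(intensities_path, samples_path) -> ExpressionMatrix:
    intensities = pd.read_csv(intensities_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    return ExpressionMatrix(intensities=intensities, samples=samples)


def write_expression(matrix: ExpressionMatrix, intensities_path, samples_path) -> None:
    matrix.intensities.to_csv(intensities_path, sep="\t")
    matrix.samples.to_csv(samples_path, sep="\t", index=False)


def bias_calls_frame(calls: Iterable[SexBiasCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "call": [c.call for c in calls],
            "log2_fold_change": [c.log2_fold_change for c in calls],
            "adjusted_p": [c.adjusted_p for c in calls],
        }
    )
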