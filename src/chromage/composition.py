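"""Chromosomal composition of gene gains and X-vs-autosome enrichment.

Covers the per-branch X-linked share of newly gained genes, age curves of
male-biased proportions, X-vs-autosome contingency tests, per-stage
spermatogenesis presence tables, a signed-log10 Fisher enrichment heatmap
across tissues, and the association between evolutionary strata of the X
and gene age. All p-values delegate to :mod:`chromage.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist

from .dating import AgeAssignment, BranchLadder
from .expression import PresenceCall, SexBiasCall, expressed_proportion
from .stats import (
    ContingencyTable,
    TestResult,
    chi_square_independence,
    fisher_exact,
)

OLD_STRATA = frozenset({"1", "2", "3"})
YOUNG_STRATA = frozenset({"4", "5"})


@dataclass(frozen=True)
class GenomePartition:
    """Chromosome class (X vs autosome) and optional X stratum per gene."""

    chromosome_class: Mapping[str, str]  # gene_id -> {"X", "autosome"}
    stratum: Mapping[str, str] | None = None  # X genes -> {"1".."5","PAR1","PAR2","undefined"}
    position: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        bad = set(self.chromosome_class.values()) - {"X", "autosome"}
        if bad:
            raise ValueError(f"invalid chromosome classes {sorted(bad)}")
        if self.stratum:
            non_x = [g for g in self.stratum if self.chromosome_class.get(g) != "X"]
            if non_x:
                raise ValueError(f"stratum ids on non-X genes: {non_x[:3]}")

    def is_x(self, gene_id: str) -> bool:
        try:
            return self.chromosome_class[gene_id] == "X"
        except KeyError:
            raise KeyError(f"gene {gene_id!r} missing from partition") from None


def branch_proportions(
    assignments: Sequence[AgeAssignment],
    partition: GenomePartition,
    ladder: BranchLadder,
) -> pd.DataFrame:
    """Per-branch X-linked share of gene gains with midpoint ages.

    Branches with zero gains get NaN shares (undefined, not 0).
    """
    n = ladder.n_branches
    x_counts = np.zeros(n, dtype=np.int64)
    totals = np.zeros(n, dtype=np.int64)
    for a in assignments:
        totals[a.branch] += 1
        if partition.is_x(a.gene_id):
            x_counts[a.branch] += 1
    with np.errstate(invalid="ignore"):
        share = np.where(totals > 0, x_counts / np.maximum(totals, 1), np.nan)
    return pd.DataFrame(
        {
            "branch": np.arange(n),
            "midpoint_myr": ladder.midpoints,
            "n_gained": totals,
            "n_x": x_counts,
            "x_share": share,
        }
    )


def bias_by_age(
    bias_calls: Sequence[SexBiasCall],
    assignments: Sequence[AgeAssignment],
    partition: GenomePartition,
    ladder: BranchLadder,
    min_covered: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-branch male-biased proportions for X and autosomes vs age.

    Only assayed genes count; a (branch, class) point with fewer than
    ``min_covered`` assayed genes is omitted. Returns (points, regressions)
    where regressions holds the least-squares slope/intercept of proportion
    on midpoint age for each chromosome class.
    """
    branch_of = {a.gene_id: a.branch for a in assignments}
    rows = []
    tallies: dict[tuple[int, str], list[int]] = {}
    for c in bias_calls:
        if c.call == "not_assayed":
            continue
        if c.gene_id not in branch_of:
            continue
        key = (branch_of[c.gene_id], "X" if partition.is_x(c.gene_id) else "autosome")
        n_total, n_male = tallies.setdefault(key, [0, 0])
        tallies[key][0] = n_total + 1
        tallies[key][1] = n_male + (c.call == "male")
    for (branch, chrom_class), (n_total, n_male) in sorted(tallies.items()):
        if n_total < min_covered:
            continue
        rows.append(
            {
                "branch": branch,
                "chromosome_class": chrom_class,
                "midpoint_myr": ladder.branches[branch].midpoint,
                "n_assayed": n_total,
                "n_male": n_male,
                "male_proportion": n_male / n_total,
            }
        )
    points = pd.DataFrame(
        rows,
        columns=[
            "branch", "chromosome_class", "midpoint_myr",
            "n_assayed", "n_male", "male_proportion",
        ],
    )
    reg_rows = []
    for chrom_class, grp in points.groupby("chromosome_class"):
        if len(grp) >= 2:
            # weight branch points by the number of assayed genes behind them
            slope, intercept = np.polyfit(
                grp["midpoint_myr"], grp["male_proportion"], 1,
                w=np.sqrt(grp["n_assayed"]),
            )
        else:
            slope = intercept = float("nan")
        reg_rows.append(
            {"chromosome_class": chrom_class, "slope": slope, "intercept": intercept}
        )
    return points, pd.DataFrame(reg_rows, columns=["chromosome_class", "slope", "intercept"])


def bias_contingency(
    gene_ids: Iterable[str],
    partition: GenomePartition,
    bias_calls: Sequence[SexBiasCall],
) -> tuple[ContingencyTable, TestResult]:
    """X/autosome x male/female/unbiased table with a chi-square test.

    ``not_assayed`` genes are excluded; an empty table after exclusion is
    an error.
    """
    wanted = set(gene_ids)
    counts = np.zeros((2, 3), dtype=np.int64)
    cols = {"male": 0, "female": 1, "unbiased": 2}
    n_used = 0
    for c in bias_calls:
        if c.gene_id not in wanted or c.call == "not_assayed":
            continue
        row = 0 if partition.is_x(c.gene_id) else 1
        counts[row, cols[c.call]] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no assayed genes left in the requested subset")
    table = ContingencyTable(
        counts,
        row_labels=("X", "autosome"),
        col_labels=("male", "female", "unbiased"),
    )
    return table, chi_square_independence(table)


def stage_presence_table(
    presence_by_stage: Mapping[str, Sequence[PresenceCall]],
    young: Mapping[str, bool],
    partition: GenomePartition,
) -> pd.DataFrame:
    """Expressed proportions and X-vs-autosome chi-square per stage and age.

    One row per (age_class, stage): present/(present+absent) proportions
    for X and autosomes (ambiguous excluded) plus the 2x2 chi-square p.
    Cells with no informative gene carry NaN and undefined=True.
    """
    rows = []
    for age_class, is_young in (("old", False), ("young", True)):
        for stage, calls in presence_by_stage.items():
            split: dict[str, list[PresenceCall]] = {"X": [], "autosome": []}
            for c in calls:
                if c.gene_id in young and young[c.gene_id] == is_young:
                    split["X" if partition.is_x(c.gene_id) else "autosome"].append(c)
            cell = {"age_class": age_class, "stage": stage}
            counts = {}
            for chrom_class, sub in split.items():
                n_present = sum(1 for c in sub if c.call == "present")
                n_absent = sum(1 for c in sub if c.call == "absent")
                counts[chrom_class] = (n_present, n_absent)
                cell[f"{chrom_class}_present"] = n_present
                cell[f"{chrom_class}_absent"] = n_absent
                cell[f"{chrom_class}_proportion"] = expressed_proportion(sub)
            informative = all(sum(counts[k]) > 0 for k in ("X", "autosome"))
            cell["undefined"] = not informative
            if informative:
                table = ContingencyTable(
                    np.array([counts["X"], counts["autosome"]]),
                    row_labels=("X", "autosome"),
                    col_labels=("present", "absent"),
                )
                try:
                    cell["p_value"] = chi_square_independence(table).p_value
                except ValueError:
                    cell["p_value"] = float("nan")
            else:
                cell["p_value"] = float("nan")
            rows.append(cell)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentCell:
    branch: int
    tissue: str
    score: float  # signed log10 p; positive = X overrepresented
    p_value: float
    informative: bool = True


def enrichment_heatmap(
    presence_by_tissue: Mapping[str, Sequence[PresenceCall]],
    assignments: Sequence[AgeAssignment],
    partition: GenomePartition,
    ladder: BranchLadder,
    clamp: float = 8.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Signed -log10 Fisher p per (branch, tissue), clamped at +/-clamp.

    For each cell a 2x2 Fisher exact test asks whether X-linked and
    autosomal genes gained in that branch are expressed (present vs
    absent, ambiguous dropped) in that tissue in the same proportions.
    Positive score = X proportion higher. Returns (branch x tissue score
    matrix, tissue order from average-linkage clustering on Euclidean
    distance between score columns).
    """
    branch_of = {a.gene_id: a.branch for a in assignments}
    tissues = list(presence_by_tissue)
    n = ladder.n_branches
    scores = pd.DataFrame(
        np.nan, index=pd.RangeIndex(n, name="branch"), columns=tissues
    )
    for tissue, calls in presence_by_tissue.items():
        counts = np.zeros((n, 2, 2), dtype=np.int64)
        for c in calls:
            if c.call == "ambiguous" or c.gene_id not in branch_of:
                continue
            b = branch_of[c.gene_id]
            row = 0 if partition.is_x(c.gene_id) else 1
            col = 0 if c.call == "present" else 1
            counts[b, row, col] += 1
        for b in range(n):
            cell = counts[b]
            if cell.sum() == 0:
                continue  # uninformative cell stays NaN
            table = ContingencyTable(
                cell, row_labels=("X", "autosome"), col_labels=("present", "absent")
            )
            p = fisher_exact(table, sided="two").p_value
            x_prop = cell[0, 0] / cell[0].sum() if cell[0].sum() else np.nan
            a_prop = cell[1, 0] / cell[1].sum() if cell[1].sum() else np.nan
            sign = 1.0 if (np.isnan(a_prop) or x_prop > a_prop) else -1.0
            if np.isnan(x_prop):
                sign = -1.0
            magnitude = min(-np.log10(max(p, 1e-300)), clamp)
            scores.loc[b, tissue] = sign * magnitude
    order = _cluster_tissues(scores)
    return scores, order


def _cluster_tissues(scores: pd.DataFrame) -> list[str]:
    """Average-linkage order of tissues on Euclidean column distance."""
    tissues = list(scores.columns)
    if len(tissues) < 3:
        return tissues
    filled = scores.fillna(0.0).to_numpy().T  # tissues x branches
    link = _hier.linkage(pdist(filled, metric="euclidean"), method="average")
    leaves = _hier.leaves_list(link)
    return [tissues[i] for i in leaves]


def strata_age_association(
    assignments: Sequence[AgeAssignment],
    partition: GenomePartition,
    young: Mapping[str, bool],
) -> tuple[ContingencyTable, TestResult]:
    """Old strata (1-3) vs young strata (4-5) against old vs young genes.

    PAR and undefined-stratum genes are excluded. One-sided Fisher tests
    whether young genes are overrepresented in the young strata.
    """
    if not partition.stratum:
        raise ValueError("partition carries no stratum annotations")
    counts = np.zeros((2, 2), dtype=np.int64)
    for a in assignments:
        stratum = partition.stratum.get(a.gene_id)
        if stratum is None or stratum not in OLD_STRATA | YOUNG_STRATA:
            continue
        row = 0 if stratum in YOUNG_STRATA else 1
        col = 0 if young.get(a.gene_id, False) else 1
        counts[row, col] += 1
    if counts.sum() == 0:
        raise ValueError("no genes with informative stratum assignments")
    table = ContingencyTable(
        counts,
        row_labels=("strata_4_5", "strata_1_3"),
        col_labels=("young_gene", "old_gene"),
    )
    return table, fisher_exact(table, sided="one_greater")


def read_strata_bed(path_or_buf) -> list[tuple[str, int, int, str]]:
    """BED file of X strata/PAR regions: chrom, start, end, name."""
    df = pd.read_csv(
        path_or_buf, sep="\t", header=None,
        names=["chrom", "start", "end", "name"], dtype={"chrom": str, "name": str},
    )
    return [
        (str(r.chrom), int(r.start), int(r.end), str(r.name)) for r in df.itertuples()
    ]


def assign_strata(
    partition: GenomePartition,
    regions: Sequence[tuple[str, int, int, str]],
    x_chrom_name: str = "X",
) -> GenomePartition:
    """Annotate X genes with the stratum whose region contains them."""
    if partition.position is None:
        raise ValueError("partition carries no gene positions")
    stratum: dict[str, str] = {}
    for gene_id, chrom_class in partition.chromosome_class.items():
        if chrom_class != "X":
            continue
        pos = partition.position.get(gene_id)
        label = "undefined"
        if pos is not None:
            for chrom, start, end, name in regions:
                if chrom == x_chrom_name and start <= pos < end:
                    label = name
                    break
        stratum[gene_id] = label
    return GenomePartition(
        chromosome_class=partition.chromosome_class,
        stratum=stratum,
        position=partition.position,
    )
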