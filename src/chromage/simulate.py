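"""Synthetic genomes and expression data with the statistical structure
the analysis assumes.

The generator stands in for the genome-annotation, synteny and microarray
inputs of a real study, so every downstream stage can be exercised and
round-tripped against known truth. It emulates:

* a two-peak history of X-linked gene gain (baseline X share ~3% of gains
  per branch, with peaks of 8-14% around the birth of the X and in the
  youngest branches),
* per-branch male-bias proportions following the exponential decay model
  on the X and a flat level on autosomes,
* MSCI-style silencing of old X-linked genes in meiotic and post-meiotic
  spermatogenic cells, with young X-linked genes instead boosted
  post-meiotically,
* replicate-level detection noise and log-normal intensity noise,
* assembly-gap dropout in ortholog evidence (calls flipped to missing),
* origin mechanisms (DNA-level duplicate / retrogene / de novo) realised
  as consistent gene models and paralog hits.

All randomness flows from ``SimulationConfig.seed``; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dating import BranchLadder, OrthologEvidence, default_human_ladder
from .divergence import DecayModel
from .expression import ExpressionMatrix
from .origins import GeneModel, ParalogHit
from .composition import GenomePartition

SPERMATOGENESIS_STAGES = (
    "type_a_spermatogonia",
    "type_b_spermatogonia",
    "pachytene_spermatocyte",
    "round_spermatid",
)

SOMATIC_TISSUES = (
    "brain", "heart", "kidney", "liver", "lung", "muscle", "spleen", "thymus",
)

# Synthetic X chromosome layout (bp): PAR1, young strata at the tip, old
# strata toward the other end, PAR2 terminal.
X_REGIONS = (
    ("X", 0, 2_700_000, "PAR1"),
    ("X", 2_700_000, 10_000_000, "5"),
    ("X", 10_000_000, 25_000_000, "4"),
    ("X", 25_000_000, 90_000_000, "3"),
    ("X", 90_000_000, 130_000_000, "2"),
    ("X", 130_000_000, 154_000_000, "1"),
    ("X", 154_000_000, 155_000_000, "PAR2"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the human panel: ~19,900 genes over 13 branches with
    most genes predating the vertebrate radiation, an X share of gains of
    3% outside two peak intervals reaching 8-14% inside them, X male-bias
    proportions following the fitted human decay model, and a flat 30%
    male-bias level on autosomes.
    """

    seed: int = 0
    gene_counts: tuple[int, ...] = (
        13800, 450, 400, 500, 700, 1300, 450, 450, 600, 350, 250, 240, 389,
    )
    x_share_baseline: float = 0.03
    x_share_peaks: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.12, 6: 0.10, 7: 0.08, 11: 0.10, 12: 0.14}
    )
    # male-bias proportion vs branch midpoint age
    male_bias_x: DecayModel = field(
        default_factory=lambda: DecayModel(N=0.74, r=0.08, d=0.42)
    )
    male_bias_autosome: DecayModel = field(
        default_factory=lambda: DecayModel(N=0.30, r=0.0, d=1.0)
    )
    female_fraction: float = 0.15
    # origin-mechanism mixture for young genes (DNA duplication dominates)
    mechanism_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"dna_duplicate": 0.80, "retrogene": 0.12,
                                 "de_novo": 0.08}
    )
    young_cutoff_branch: int = 8
    # spermatogenesis presence probabilities (autosomal baseline per stage)
    stage_presence_old: Mapping[str, float] = field(
        default_factory=lambda: {
            "type_a_spermatogonia": 0.64, "type_b_spermatogonia": 0.67,
            "pachytene_spermatocyte": 0.57, "round_spermatid": 0.57,
        }
    )
    stage_presence_young: Mapping[str, float] = field(
        default_factory=lambda: {
            "type_a_spermatogonia": 0.18, "type_b_spermatogonia": 0.22,
            "pachytene_spermatocyte": 0.23, "round_spermatid": 0.27,
        }
    )
    #: probability that an old X-linked gene otherwise expressed in a
    #: meiotic/post-meiotic stage is silenced there (MSCI)
    msci_silencing_prob: float = 0.40
    #: presence probability of young X genes in round spermatid (escape
    #: from MSCI; boosted relative to young autosomal genes)
    young_x_postmeiotic_presence: float = 0.70
    n_replicates: int = 4
    n_stage_replicates: int = 2
    log2_noise_sd: float = 0.35
    bias_effect_log2: float = 2.0
    expressed_log2_mean: float = 7.0
    background_log2_mean: float = 3.0
    background_log2_sd: float = 0.8
    background_pool_size: int = 150
    ortholog_dropout: float = 0.10
    #: log2-sd of between-species multiplicative drift, and the inflated
    #: value applied to young X genes in round spermatid
    species_drift_sd: float = 0.3
    species_drift_sd_young_x: float = 1.2
    # strata placement: P(old-strata 1-3) for old vs young X genes, PAR rate
    strata_old_bias: float = 0.75
    strata_young_bias: float = 0.55
    par_fraction: float = 0.02

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.gene_counts):
            raise ValueError("gene counts must be >= 0")
        if sum(self.gene_counts) == 0:
            raise ValueError("at least one gene must be simulated")
        probs = [
            self.x_share_baseline, self.female_fraction,
            self.msci_silencing_prob, self.young_x_postmeiotic_presence,
            self.ortholog_dropout, self.par_fraction,
            *self.x_share_peaks.values(), *self.mechanism_mixture.values(),
            *self.stage_presence_old.values(), *self.stage_presence_young.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0.0 <= self.ortholog_dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if abs(sum(self.mechanism_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mechanism mixture must sum to 1")

    def x_share(self, branch: int) -> float:
        return self.x_share_peaks.get(branch, self.x_share_baseline)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "male_bias_x" in raw:
            raw["male_bias_x"] = DecayModel(**raw["male_bias_x"])
        if "male_bias_autosome" in raw:
            raw["male_bias_autosome"] = DecayModel(**raw["male_bias_autosome"])
        if "gene_counts" in raw:
            raw["gene_counts"] = tuple(raw["gene_counts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["gene_counts"] = list(self.gene_counts)
        raw["x_share_peaks"] = dict(self.x_share_peaks)
        raw["mechanism_mixture"] = dict(self.mechanism_mixture)
        raw["stage_presence_old"] = dict(self.stage_presence_old)
        raw["stage_presence_young"] = dict(self.stage_presence_young)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class SyntheticGenome:
    """Truth table plus the derived inputs every stage consumes."""

    truth: pd.DataFrame  # gene_id, branch, chromosome_class, stratum,
    #                      mechanism, bias, stage_<name> booleans
    partition: GenomePartition
    models: dict[str, GeneModel]  # child gene models
    parents: dict[str, GeneModel]
    hits: list[ParalogHit]
    ladder: BranchLadder


def simulate_genome(
    config: SimulationConfig, ladder: BranchLadder | None = None
) -> SyntheticGenome:
    """Draw a genome: branches, chromosome classes, strata, mechanisms,
    true sex bias, and true spermatogenesis expression patterns."""
    ladder = ladder or default_human_ladder()
    if len(config.gene_counts) != ladder.n_branches:
        raise ValueError(
            f"config has {len(config.gene_counts)} branch counts but the "
            f"ladder has {ladder.n_branches} branches"
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    for branch, count in enumerate(config.gene_counts):
        midpoint = ladder.branches[branch].midpoint
        x_p = config.x_share(branch)
        is_young = branch >= config.young_cutoff_branch
        p_male_x = config.male_bias_x(midpoint)
        p_male_a = config.male_bias_autosome(midpoint)
        for k in range(count):
            gene_id = f"g{branch:02d}_{k:05d}"
            on_x = rng.random() < x_p
            p_male = p_male_x if on_x else p_male_a
            u = rng.random()
            if u < p_male:
                bias = "male"
            elif u < p_male + config.female_fraction:
                bias = "female"
            else:
                bias = "unbiased"
            rows.append(
                {
                    "gene_id": gene_id,
                    "branch": branch,
                    "chromosome_class": "X" if on_x else "autosome",
                    "young": is_young,
                    "bias": bias,
                }
            )
    truth = pd.DataFrame(rows)
    truth["stratum"] = [
        _draw_stratum(rng, config, r.chromosome_class, r.young)
        for r in truth.itertuples()
    ]
    truth["mechanism"] = [
        rng.choice(
            list(config.mechanism_mixture),
            p=list(config.mechanism_mixture.values()),
        )
        if r.young
        else "none"
        for r in truth.itertuples()
    ]
    for stage in SPERMATOGENESIS_STAGES:
        truth[f"stage_{stage}"] = [
            _draw_stage_presence(rng, config, stage, r.chromosome_class, r.young)
            for r in truth.itertuples()
        ]
    positions = _draw_positions(rng, truth)
    partition = GenomePartition(
        chromosome_class=dict(zip(truth.gene_id, truth.chromosome_class)),
        stratum={
            g: s
            for g, s, c in zip(truth.gene_id, truth.stratum, truth.chromosome_class)
            if c == "X"
        },
        position=positions,
    )
    models, parents, hits = _draw_gene_models(rng, truth, positions)
    return SyntheticGenome(
        truth=truth, partition=partition, models=models, parents=parents,
        hits=hits, ladder=ladder,
    )


def _draw_stratum(rng, config: SimulationConfig, chrom_class: str, young: bool) -> str:
    if chrom_class != "X":
        return "none"
    if rng.random() < config.par_fraction:
        return "PAR1" if rng.random() < 0.5 else "PAR2"
    old_bias = config.strata_old_bias if not young else 1.0 - config.strata_young_bias
    if rng.random() < old_bias:
        return rng.choice(["1", "2", "3"])
    return rng.choice(["4", "5"])


def _draw_stage_presence(
    rng, config: SimulationConfig, stage: str, chrom_class: str, young: bool
) -> bool:
    if young:
        base = config.stage_presence_young[stage]
        if chrom_class == "X" and stage == "round_spermatid":
            base = config.young_x_postmeiotic_presence
        elif chrom_class == "X":
            base = min(1.0, base * 1.6)  # young X somewhat testis-prone overall
        return bool(rng.random() < base)
    base = config.stage_presence_old[stage]
    expressed = rng.random() < base
    if (
        expressed
        and chrom_class == "X"
        and stage in ("pachytene_spermatocyte", "round_spermatid")
    ):
        # MSCI: silence old X genes from meiosis onward
        expressed = rng.random() >= config.msci_silencing_prob
    return bool(expressed)


_STRATUM_SPANS = {name: (start, end) for _, start, end, name in X_REGIONS}


def _draw_positions(rng, truth: pd.DataFrame) -> dict[str, int]:
    positions: dict[str, int] = {}
    for r in truth.itertuples():
        if r.chromosome_class == "X":
            start, end = _STRATUM_SPANS.get(r.stratum, (0, 155_000_000))
            positions[r.gene_id] = int(rng.integers(start, end))
        else:
            positions[r.gene_id] = int(rng.integers(0, 240_000_000))
    return positions


def _draw_gene_models(
    rng, truth: pd.DataFrame, positions: Mapping[str, int]
) -> tuple[dict[str, GeneModel], dict[str, GeneModel], list[ParalogHit]]:
    """Gene models and paralog hits consistent with the drawn mechanisms.

    Each young duplicate gets one qualifying hit against a dedicated
    parent; retrogene parents carry introns inside the aligned interval
    while the retrogene child is single-exon; DNA-level duplicates keep at
    least one intron in the aligned span. De novo genes receive no hits.
    """
    models: dict[str, GeneModel] = {}
    parents: dict[str, GeneModel] = {}
    hits: list[ParalogHit] = []
    for r in truth.itertuples():
        pos = positions[r.gene_id]
        chrom = "X" if r.chromosome_class == "X" else "1"
        if r.mechanism == "retrogene":
            exons = ((pos, pos + 1500),)
        else:
            exons = (
                (pos, pos + 300),
                (pos + 800, pos + 1100),
                (pos + 1600, pos + 1900),
            )
        models[r.gene_id] = GeneModel(
            gene_id=r.gene_id, chromosome=chrom,
            strand="+" if rng.random() < 0.5 else "-", exons=exons,
        )
        if r.mechanism in ("retrogene", "dna_duplicate"):
            parent_id = f"parent_{r.gene_id}"
            p_pos = int(rng.integers(0, 200_000_000))
            parents[parent_id] = GeneModel(
                gene_id=parent_id, chromosome="2", strand="+",
                exons=(
                    (p_pos, p_pos + 400),
                    (p_pos + 900, p_pos + 1300),
                    (p_pos + 2000, p_pos + 2400),
                ),
            )
            span = models[r.gene_id].span
            hits.append(
                ParalogHit(
                    child_id=r.gene_id, parent_id=parent_id,
                    child_interval=span,
                    parent_interval=(p_pos, p_pos + 2400),
                    e_value=float(10.0 ** rng.uniform(-50, -10)),
                )
            )
    return models, parents, hits


def simulate_ortholog_evidence(
    genome: SyntheticGenome,
    dropout: float | None = None,
    seed: int | None = None,
) -> list[OrthologEvidence]:
    """Staircase ortholog calls with independent missing-call dropout.

    A gene born on branch ``b`` is present in every outgroup joining at
    split ``b`` or later and absent in more ancestral outgroups; each
    non-focal call then flips to ``missing`` independently with
    probability ``dropout`` (assembly gaps, unreliable synteny).
    """
    config_dropout = dropout if dropout is not None else 0.0
    if not 0.0 <= config_dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed if seed is not None else 0)
    ladder = genome.ladder
    split_species = [
        (b.index, sorted(b.outgroups)) for b in ladder.branches[:-1]
    ]
    out = []
    for r in genome.truth.itertuples():
        calls: dict[str, str] = {}
        for split_idx, species in split_species:
            state = "present" if split_idx >= r.branch else "absent"
            for sp in species:
                calls[sp] = (
                    "missing" if rng.random() < config_dropout else state
                )
        out.append(OrthologEvidence(gene_id=r.gene_id, calls=calls))
    return out


@dataclass(frozen=True)
class SyntheticExpression:
    """Expression matrices for every assay the analysis consumes."""

    gonads: ExpressionMatrix  # testis + ovary replicates
    somatic: ExpressionMatrix  # 8 somatic tissues + ovary
    spermatogenesis: dict[str, ExpressionMatrix]  # species -> 4 cell types
    background: np.ndarray  # shared background signal pool


def simulate_expression(
    genome: SyntheticGenome, config: SimulationConfig
) -> SyntheticExpression:
    """Log-normal intensities with planted bias, MSCI and species drift."""
    rng = np.random.default_rng(config.seed + 1)
    truth = genome.truth
    n_genes = len(truth)
    gene_ids = list(truth.gene_id)
    base = rng.normal(config.expressed_log2_mean, 1.0, size=n_genes)

    # --- gonads -----------------------------------------------------------
    effect = np.zeros(n_genes)
    effect[truth.bias.to_numpy() == "male"] = config.bias_effect_log2
    effect[truth.bias.to_numpy() == "female"] = -config.bias_effect_log2
    t_cols = {}
    for i in range(config.n_replicates):
        t_cols[f"testis_{i + 1}"] = _linear(
            rng, base + effect / 2.0, config.log2_noise_sd
        )
        t_cols[f"ovary_{i + 1}"] = _linear(
            rng, base - effect / 2.0, config.log2_noise_sd
        )
    gonads = _matrix(gene_ids, t_cols, _gonad_sheet(config))

    # --- somatic tissues + ovary (RA comparisons) -------------------------
    tissues = SOMATIC_TISSUES + ("ovary",)
    weights = rng.dirichlet(np.ones(len(tissues)), size=n_genes)
    ovary_idx = len(tissues) - 1
    is_x = truth.chromosome_class.to_numpy() == "X"
    is_young = truth.young.to_numpy()
    # feminization of the X with age: old X genes gain, young X genes lack,
    # ovary expression relative to autosomal genes of the same age
    weights[is_x & ~is_young, ovary_idx] *= 2.0
    weights[is_x & is_young, ovary_idx] *= 0.3
    weights /= weights.sum(axis=1, keepdims=True)
    som_cols = {}
    for j, tissue in enumerate(tissues):
        mean_log2 = base + np.log2(np.maximum(weights[:, j], 1e-6) * len(tissues))
        for i in range(config.n_stage_replicates):
            som_cols[f"{tissue}_{i + 1}"] = _linear(rng, mean_log2, config.log2_noise_sd)
    somatic = _matrix(
        gene_ids, som_cols, _tissue_sheet(tissues, config.n_stage_replicates)
    )

    # --- spermatogenesis, two species -------------------------------------
    stage_mean = {}
    for stage in SPERMATOGENESIS_STAGES:
        expressed = truth[f"stage_{stage}"].to_numpy()
        stage_mean[stage] = np.where(
            expressed, base, rng.normal(
                config.background_log2_mean, config.background_log2_sd, n_genes
            )
        )
    spermatogenesis = {}
    for species in ("mouse", "rat"):
        cols = {}
        for stage in SPERMATOGENESIS_STAGES:
            mean_log2 = stage_mean[stage].copy()
            if species == "rat":
                drift_sd = np.full(n_genes, config.species_drift_sd)
                if stage == "round_spermatid":
                    drift_sd[is_x & is_young] = config.species_drift_sd_young_x
                mean_log2 = mean_log2 + rng.normal(0.0, 1.0, n_genes) * drift_sd
            for i in range(config.n_stage_replicates):
                cols[f"{stage}_{i + 1}"] = _linear(
                    rng, mean_log2, config.log2_noise_sd
                )
        spermatogenesis[species] = _matrix(
            gene_ids, cols,
            _tissue_sheet(SPERMATOGENESIS_STAGES, config.n_stage_replicates,
                          species=species),
        )

    background = _linear(
        rng,
        rng.normal(config.background_log2_mean, config.background_log2_sd,
                   config.background_pool_size),
        config.log2_noise_sd,
    )
    return SyntheticExpression(
        gonads=gonads, somatic=somatic, spermatogenesis=spermatogenesis,
        background=background,
    )


def _linear(rng, mean_log2: np.ndarray, sd: float) -> np.ndarray:
    return 2.0 ** (mean_log2 + rng.normal(0.0, sd, size=mean_log2.shape))


def _matrix(gene_ids, cols: dict[str, np.ndarray], sheet: pd.DataFrame) -> ExpressionMatrix:
    frame = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(intensities=frame[list(sheet["sample"])], samples=sheet)


def _gonad_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for tissue in ("testis", "ovary"):
        for i in range(config.n_replicates):
            rows.append(
                {
                    "sample": f"{tissue}_{i + 1}", "tissue": tissue,
                    "replicate_group": tissue, "species": "mouse",
                }
            )
    return pd.DataFrame(rows)


def _tissue_sheet(
    tissues: Sequence[str], n_replicates: int, species: str = "mouse"
) -> pd.DataFrame:
    rows = []
    for tissue in tissues:
        for i in range(n_replicates):
            rows.append(
                {
                    "sample": f"{tissue}_{i + 1}", "tissue": tissue,
                    "replicate_group": tissue, "species": species,
                }
            )
    return pd.DataFrame(rows)


def strata_bed_frame() -> pd.DataFrame:
    """The synthetic X strata/PAR map as a BED-like frame."""
    return pd.DataFrame(X_REGIONS, columns=["chrom", "start", "end", "name"])
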