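"""Classify young genes by origination mechanism.

Three mechanisms are distinguished from paralog hits and intron structure:

* ``de_novo`` — no paralog hit at the e-value cutoff (1e-6) and no
  annotated paralog,
* ``retrogene`` — the best-hit parental gene carries at least one intron
  inside the aligned interval while the child is intronless there
  (retroposition through an mRNA intermediate strips introns),
* ``dna_duplicate`` — everything else with a qualifying hit.

Coordinates are 0-based half-open base pairs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

EVALUE_CUTOFF = 1e-6

Mechanism = str  # {"dna_duplicate", "retrogene", "de_novo"}
MECHANISMS = ("dna_duplicate", "retrogene", "de_novo")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene; introns are the gaps between exons."""

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >= 1 exon")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty/inverted exon [{s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class ParalogHit:
    """One BLAST-like alignment between a child gene and a candidate parent."""

    child_id: str
    parent_id: str
    child_interval: tuple[int, int]
    parent_interval: tuple[int, int]
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e-value must be > 0")
        for s, e in (self.child_interval, self.parent_interval):
            if s >= e:
                raise ValueError("aligned interval is empty or inverted")


def introns_in_interval(model: GeneModel, interval: tuple[int, int]) -> int:
    """Number of introns *fully contained* in ``interval``."""
    s, e = interval
    if s >= e:
        raise ValueError(f"inverted interval [{s}, {e})")
    return sum(1 for (i0, i1) in model.introns if s <= i0 and i1 <= e)


def best_hit(hits: Iterable[ParalogHit]) -> ParalogHit | None:
    """Lowest e-value at the cutoff; ties go to the longer aligned span,
    then the lexically smaller parent id."""
    qualifying = [h for h in hits if h.e_value <= EVALUE_CUTOFF]
    if not qualifying:
        return None
    return min(
        qualifying,
        key=lambda h: (
            h.e_value,
            -(h.child_interval[1] - h.child_interval[0]),
            h.parent_id,
        ),
    )


def classify_origin(
    child: GeneModel,
    hits: Iterable[ParalogHit],
    parents: Mapping[str, GeneModel],
    has_annotated_paralog: bool = False,
) -> Mechanism:
    """Assign one of ``dna_duplicate`` / ``retrogene`` / ``de_novo``."""
    hit = best_hit(hits)
    if hit is None:
        return "dna_duplicate" if has_annotated_paralog else "de_novo"
    if hit.parent_id not in parents:
        raise KeyError(f"best hit references unknown parent {hit.parent_id!r}")
    parent = parents[hit.parent_id]
    parent_introns = introns_in_interval(parent, hit.parent_interval)
    child_introns = introns_in_interval(child, hit.child_interval)
    if parent_introns >= 1 and child_introns == 0:
        return "retrogene"
    return "dna_duplicate"


def classify_genome(
    children: Mapping[str, GeneModel],
    hits: Iterable[ParalogHit],
    parents: Mapping[str, GeneModel],
    annotated_paralogs: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Classify every child gene; returns gene_id/mechanism columns."""
    by_child: dict[str, list[ParalogHit]] = {g: [] for g in children}
    for h in hits:
        if h.child_id in by_child:
            by_child[h.child_id].append(h)
    rows = [
        {
            "gene_id": gene_id,
            "mechanism": classify_origin(
                model, by_child[gene_id], parents, gene_id in annotated_paralogs
            ),
        }
        for gene_id, model in children.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "mechanism"])


# ---------------------------------------------------------------------------
# I/O: exon tables and 7-column hit tables


def read_gene_models_tsv(path_or_buf) -> dict[str, GeneModel]:
    """Exon-table TSV: gene_id, chromosome, strand, exon_start, exon_end."""
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {"gene_id", "chromosome", "strand", "exon_start", "exon_end"}
    if not required <= set(df.columns):
        raise ValueError(f"gene-model TSV needs columns {sorted(required)}")
    models: dict[str, GeneModel] = {}
    for gene_id, grp in df.groupby("gene_id", sort=False):
        grp = grp.sort_values("exon_start")
        models[str(gene_id)] = GeneModel(
            gene_id=str(gene_id),
            chromosome=str(grp["chromosome"].iloc[0]),
            strand=str(grp["strand"].iloc[0]),
            exons=tuple(
                (int(s), int(e)) for s, e in zip(grp["exon_start"], grp["exon_end"])
            ),
        )
    return models


def write_gene_models_tsv(models: Iterable[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "chromosome": m.chromosome,
            "strand": m.strand,
            "exon_start": s,
            "exon_end": e,
        }
        for m in models
        for s, e in m.exons
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "strand", "exon_start", "exon_end"]
    ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path_or_buf) -> list[ParalogHit]:
    """Hit TSV: child, parent, child_start, child_end, parent_start,
    parent_end, evalue."""
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {
        "child", "parent", "child_start", "child_end",
        "parent_start", "parent_end", "evalue",
    }
    if not required <= set(df.columns):
        raise ValueError(f"hit TSV needs columns {sorted(required)}")
    return [
        ParalogHit(
            child_id=str(r.child),
            parent_id=str(r.parent),
            child_interval=(int(r.child_start), int(r.child_end)),
            parent_interval=(int(r.parent_start), int(r.parent_end)),
            e_value=float(r.evalue),
        )
        for r in df.itertuples()
    ]
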