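"""Gene-age dating on a species ladder by parsimony.

A gene is dated by the presence/absence of syntenic orthologs in a series
of progressively closer outgroups of the focal species (a "ladder" tree:
each speciation split on the path from the root to the focal tip peels off
one outgroup clade). The gene's origination branch is the interval between
two consecutive splits.

The parsimony rule assumes a single origination event. Scoring every
candidate branch with unit gain and loss costs, the optimum is the split
of the most ancestral outgroup carrying a present call; absences crownward
of it are counted as losses, missing calls are uninformative, and cost
ties are broken toward the older branch (so a run of missing calls just
beyond the most ancestral presence pushes the assignment older).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

Call = str  # {"present", "absent", "missing"}
VALID_CALLS = frozenset({"present", "absent", "missing"})


class UnassignableError(ValueError):
    """All ortholog calls for a gene are missing."""


class SchemaError(ValueError):
    """Input does not match the expected schema."""


@dataclass(frozen=True)
class Branch:
    """One rung of the ladder: the lineage interval after a given split."""

    index: int
    outgroups: frozenset[str]  # clade that diverged at the split opening this branch
    age_start: float  # older bound, myr (negative = past)
    age_end: float  # younger bound, myr
    midpoint: float  # plotting/fitting age, myr


@dataclass(frozen=True)
class BranchLadder:
    """Ordered speciation splits with outgroup sets and midpoint ages.

    Branch indices increase toward the present. The last branch is
    focal-species-specific and has no outgroup. The oldest branch's
    midpoint is conventionally pinned at -500 myr.
    """

    focal: str
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        idx = [b.index for b in self.branches]
        if idx != list(range(len(self.branches))):
            raise ValueError("branch indices must be 0..B in order")
        if len(self.branches) < 2:
            raise ValueError("ladder needs at least 2 branches")
        if self.branches[-1].outgroups:
            raise ValueError("youngest branch must be focal-specific (no outgroup)")
        for b in self.branches[:-1]:
            if not b.outgroups:
                raise ValueError(f"branch {b.index} has an empty outgroup set")
        seen: set[str] = set()
        for b in self.branches[:-1]:
            if b.outgroups & seen:
                raise ValueError("outgroup species appear in more than one split")
            seen |= b.outgroups
        mids = [b.midpoint for b in self.branches]
        if any(a >= b for a, b in zip(mids, mids[1:])):
            raise ValueError("branch midpoints must increase toward the present")

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def youngest(self) -> int:
        return len(self.branches) - 1

    @property
    def species(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.branches:
            out |= b.outgroups
        return frozenset(out)

    def split_index_of(self, species: str) -> int:
        for b in self.branches:
            if species in b.outgroups:
                return b.index
        raise SchemaError(f"species {species!r} not on the ladder")

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.branches], dtype=float)


@dataclass(frozen=True)
class OrthologEvidence:
    """Per-species ortholog calls for one gene."""

    gene_id: str
    calls: Mapping[str, Call]

    def __post_init__(self) -> None:
        bad = {v for v in self.calls.values()} - VALID_CALLS
        if bad:
            raise SchemaError(f"invalid ortholog calls {sorted(bad)} for {self.gene_id}")


@dataclass(frozen=True)
class AgeAssignment:
    gene_id: str
    branch: int
    conflict_resolved: bool = False
    gap_inferred: bool = False


def assign_branch(evidence: OrthologEvidence, ladder: BranchLadder) -> AgeAssignment:
    """Date one gene by single-origin parsimony.

    Raises :class:`UnassignableError` when every call is missing and
    :class:`SchemaError` when a call names a species not on the ladder.
    """
    calls = _calls_by_split(evidence, ladder)
    n_out = ladder.youngest  # outgroup splits are 0..B-1
    informative = [j for j in range(n_out) if calls[j] != "missing"]
    if not informative:
        raise UnassignableError(
            f"gene {evidence.gene_id}: all ortholog calls missing"
        )
    present = [j for j in range(n_out) if calls[j] == "present"]
    anchor = min(present) if present else ladder.youngest
    # extend older through missing calls: all single-origin placements with
    # no additional loss are cost ties, resolved toward the older branch
    branch = anchor
    while branch > 0 and calls[branch - 1] == "missing":
        branch -= 1
    conflict = any(
        calls[j] == "absent" and any(p < j for p in present) for j in range(n_out)
    )
    return AgeAssignment(
        gene_id=evidence.gene_id,
        branch=branch,
        conflict_resolved=conflict,
        gap_inferred=branch < anchor,
    )


def _calls_by_split(evidence: OrthologEvidence, ladder: BranchLadder) -> list[Call]:
    """Collapse per-species calls to one call per outgroup split.

    Within a multi-species outgroup clade, a single present suffices
    (the gene predates the split); all-absent is absent; otherwise missing.
    """
    per_split: list[list[Call]] = [[] for _ in range(ladder.youngest)]
    for sp, call in evidence.calls.items():
        per_split[ladder.split_index_of(sp)].append(call)
    out: list[Call] = []
    for group in per_split:
        if "present" in group:
            out.append("present")
        elif group and all(c == "absent" for c in group):
            out.append("absent")
        else:
            out.append("missing")
    return out


@dataclass(frozen=True)
class GenomeAssignment:
    """Per-gene assignments plus the per-branch gain histogram."""

    assignments: tuple[AgeAssignment, ...]
    gain_counts: np.ndarray  # length B+1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in self.assignments],
                "branch": [a.branch for a in self.assignments],
                "conflict_resolved": [a.conflict_resolved for a in self.assignments],
                "gap_inferred": [a.gap_inferred for a in self.assignments],
            }
        )

    def branch_of(self) -> dict[str, int]:
        return {a.gene_id: a.branch for a in self.assignments}


def assign_genome(
    evidence_matrix: Iterable[OrthologEvidence], ladder: BranchLadder
) -> GenomeAssignment:
    """Date every gene and tally per-branch gains.

    Duplicate gene ids are rejected; genes whose calls are all missing
    raise (filter them out first if that is acceptable upstream).
    """
    seen: set[str] = set()
    assignments: list[AgeAssignment] = []
    counts = np.zeros(ladder.n_branches, dtype=np.int64)
    for ev in evidence_matrix:
        if ev.gene_id in seen:
            raise SchemaError(f"duplicate gene id {ev.gene_id!r}")
        seen.add(ev.gene_id)
        a = assign_branch(ev, ladder)
        assignments.append(a)
        counts[a.branch] += 1
    return GenomeAssignment(assignments=tuple(assignments), gain_counts=counts)


def flag_young(
    assignments: Iterable[AgeAssignment], cutoff_branch: int
) -> dict[str, bool]:
    """Young iff branch >= cutoff (e.g. cutoff 8 = primate-specific)."""
    return {a.gene_id: a.branch >= cutoff_branch for a in assignments}


# ---------------------------------------------------------------------------
# I/O


def ladder_from_newick(
    newick: str, focal: str, ages: pd.DataFrame
) -> BranchLadder:
    """Build a ladder from a Newick string and a branch-age table.

    The tree must be a ladder with respect to ``focal``: every internal
    node on the root-to-focal path has exactly two children, one being the
    next node on the path. ``ages`` needs columns branch, age_start,
    age_end, midpoint (myr, negative past), one row per branch, oldest
    first.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    focal_leaf = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == focal:
            focal_leaf = leaf
            break
    if focal_leaf is None:
        raise SchemaError(f"focal species {focal!r} not in tree")
    path = []
    node = focal_leaf
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()  # root ... focal leaf
    outgroup_sets: list[frozenset[str]] = []
    for node, child_on_path in zip(path[:-1], path[1:]):
        children = node.child_nodes()
        if len(children) != 2:
            raise SchemaError(
                "tree is not a ladder: an internal node on the focal path "
                f"has {len(children)} children"
            )
        sibling = children[0] if children[1] is child_on_path else children[1]
        labels = frozenset(
            lf.taxon.label for lf in sibling.leaf_iter() if lf.taxon is not None
        )
        outgroup_sets.append(labels)
    outgroup_sets.append(frozenset())  # focal-specific branch
    required = {"branch", "age_start", "age_end", "midpoint"}
    if not required <= set(ages.columns):
        raise SchemaError(f"age table needs columns {sorted(required)}")
    ages = ages.sort_values("branch").reset_index(drop=True)
    if len(ages) != len(outgroup_sets):
        raise SchemaError(
            f"age table has {len(ages)} rows but the tree implies "
            f"{len(outgroup_sets)} branches"
        )
    branches = tuple(
        Branch(
            index=i,
            outgroups=outgroup_sets[i],
            age_start=float(ages.age_start[i]),
            age_end=float(ages.age_end[i]),
            midpoint=float(ages.midpoint[i]),
        )
        for i in range(len(outgroup_sets))
    )
    return BranchLadder(focal=focal, branches=branches)


def read_evidence_tsv(path_or_buf) -> list[OrthologEvidence]:
    """Read long-form evidence TSV with columns gene_id, species, call."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    required = {"gene_id", "species", "call"}
    if not required <= set(df.columns):
        raise SchemaError(f"evidence TSV needs columns {sorted(required)}")
    bad = df.loc[~df["call"].isin(VALID_CALLS)]
    if not bad.empty:
        line = int(bad.index[0]) + 2  # 1-based, after header
        raise SchemaError(
            f"invalid call {bad['call'].iloc[0]!r} at line {line}"
        )
    out = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        out.append(
            OrthologEvidence(
                gene_id=str(gene_id),
                calls=dict(zip(grp["species"], grp["call"])),
            )
        )
    return out


def write_evidence_tsv(evidence: Iterable[OrthologEvidence], path) -> None:
    rows = [
        {"gene_id": ev.gene_id, "species": sp, "call": call}
        for ev in evidence
        for sp, call in ev.calls.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "species", "call"]).to_csv(
        path, sep="\t", index=False
    )


# Default human-like ladder used by the simulator and the worked examples.
# Thirteen branches; outgroup clades peel off oldest-first; split ages follow
# standard vertebrate divergence times, the youngest branch midpoint is -3
# (interval -6..0) and the oldest branch is pinned at -500.
_DEFAULT_SPLITS = [
    ("teleost_fish", -450.0),
    ("frog", -370.0),
    ("chicken", -310.0),
    ("platypus", -180.0),
    ("opossum", -160.0),
    ("afrotherian", -130.0),
    ("laurasiatherian", -90.0),
    ("rodent", -75.0),
    ("marmoset", -45.0),
    ("macaque", -30.0),
    ("orangutan", -15.0),
    ("chimpanzee", -6.0),
]


def default_human_ladder() -> BranchLadder:
    """Thirteen-branch primate ladder with a -500 myr pin on branch 0.

    Branch ``i`` is the interval between split ``i - 1`` and split ``i``;
    branch 0 predates the oldest split (present in the most distant
    outgroup), branch 12 postdates the chimp split (absent everywhere).
    """
    split_ages = [age for _, age in _DEFAULT_SPLITS] + [0.0]
    branches = []
    for i, (sp, _) in enumerate(_DEFAULT_SPLITS):
        start = -500.0 if i == 0 else split_ages[i - 1]
        end = split_ages[i]
        mid = -500.0 if i == 0 else (start + end) / 2.0
        branches.append(
            Branch(index=i, outgroups=frozenset({sp}), age_start=start,
                   age_end=end, midpoint=mid)
        )
    branches.append(
        Branch(index=len(_DEFAULT_SPLITS), outgroups=frozenset(),
               age_start=-6.0, age_end=0.0, midpoint=-3.0)
    )
    return BranchLadder(focal="human", branches=branches)


def default_ladder_newick() -> str:
    """Newick rendering of the default ladder (round-trips via
    :func:`ladder_from_newick`)."""
    tip = "human"
    for sp, _ in reversed(_DEFAULT_SPLITS):
        tip = f"({sp},{tip})"
    return tip + ";"


def default_ladder_ages() -> pd.DataFrame:
    ladder = default_human_ladder()
    return pd.DataFrame(
        {
            "branch": [b.index for b in ladder.branches],
            "age_start": [b.age_start for b in ladder.branches],
            "age_end": [b.age_end for b in ladder.branches],
            "midpoint": [b.midpoint for b in ladder.branches],
        }
    )
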