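# chromage

Gene-age dating on a vertebrate species ladder, and the age-dependent
chromosomal distribution of sex-biased genes.

## The problem

The mammalian X chromosome is hemizygous in males, which exposes it to
sex-specific selection: sexual antagonism can favour the fixation of
recessive male-beneficial alleles on the X, while meiotic sex chromosome
inactivation (MSCI) silences the X during spermatogenesis and pushes
meiotically expressed genes onto autosomes. Whether a male-biased gene
sits on the X or on an autosome therefore depends on *when it arose*:
young X-linked genes tend to be male-biased, old X-linked genes do not.

`chromage` is a pipeline for studying that redistribution. Given
ortholog presence/absence evidence across a ladder of outgroup species,
gene models, paralog hits, and replicated expression matrices, it

* dates each gene's origination branch by single-origin parsimony,
* classifies young genes into DNA-level duplicates, retrogenes
  (intronless copies of intron-bearing parents), and de novo genes,
* calls expression presence (strict all-replicates consensus) and
  testis-vs-ovary sex bias (shrinkage *t* with BH-FDR control),
* tallies per-branch chromosomal composition (the X share of gene gains),
  X-vs-autosome contingency tests, per-stage spermatogenesis presence,
  signed-log10 Fisher enrichment heatmaps, and strata-age association,
* measures cross-species expression divergence via relative abundance,
  and fits an exponential decay of male-bias proportion against gene age.

Because the raw genome/microarray inputs are large external downloads,
the package ships a first-class synthetic-data generator that emulates
their statistical structure (two-peak X-linked gene gain, decay-model
male-bias, MSCI-style silencing, replicate noise, ortholog dropout), so
every stage is testable end to end against known truth.

## The core quantities

**Parsimony dating.** Outgroups join the focal lineage at ordered splits
0..B−1 (0 = most distant). A gene's origination branch is the split index
of the most ancestral outgroup with a syntenic ortholog; absences
crownward of it are counted as losses, missing calls are uninformative,
and cost ties resolve toward the older branch. Genes at branch ≥ 8 on the
13-branch primate ladder are "young" (primate-specific).

**Relative abundance and divergence.** For a gene with intensity `I_t` in
tissue `t`, `RA_t = I_t / Σ_u I_u`; divergence between orthologs in two
species is `D = Σ_t (RA_t^A − RA_t^B)²` (0 ≤ D ≤ 2).

**Decay model.** The proportion of male-biased genes among genes born at
age `t ≤ 0` myr follows

```
f(t) = N · (e^{r·t} · (1 − d) + d)
```

with `N = f(0)` the present-day proportion, `r` the decay rate per myr,
and `N·d` the deep-time plateau. It is fitted by count-weighted nonlinear
least squares with box constraints and jittered multi-start.

## Worked example

```python
import numpy as np
from chromage import (SimulationConfig, simulate_genome,
                      simulate_ortholog_evidence, assign_genome,
                      branch_proportions, fit_decay)

config = SimulationConfig(seed=7)          # ~19,900 genes, 13 branches
genome = simulate_genome(config)
evidence = simulate_ortholog_evidence(genome, dropout=0.10, seed=8)
dated = assign_genome(evidence, genome.ladder)

truth = dict(zip(genome.truth.gene_id, genome.truth.branch))
recovery = np.mean([a.branch == truth[a.gene_id] for a in dated.assignments])
print(f"exact branch recovery at 10% evidence dropout: {recovery:.1%}")

shares = branch_proportions(dated.assignments, genome.partition, genome.ladder)
for b in (0, 5, 12):
    row = shares.iloc[b]
    print(f"branch {b:>2} ({row.midpoint_myr:+.1f} myr): "
          f"{int(row.n_gained)} gains, X share {row.x_share:.3f}")
```

prints

```
exact branch recovery at 10% evidence dropout: 97.1%
branch  0 (-500.0 myr): 13856 gains, X share 0.030
branch  5 (-145.0 myr): 1209 gains, X share 0.132
branch 12 (-3.0 myr): 344 gains, X share 0.148
```

The X share of gains sits at the ~3% baseline on the oldest branch and
peaks above 13% both around the birth of the X (branch 5) and in the
youngest branch — the two-peak signature the generator plants and the
dating recovers. Misdated genes (2.9% here) land only on branches *older*
than truth, a consequence of resolving parsimony ties toward the older
branch. Fitting the decay model to the per-branch X-linked male-bias
proportions of the same genome gives `N=0.709, r=0.034, d=0.457`, i.e.
~71% of newborn X-linked genes are male-biased but only ~32% remain so at
deep time.

The same stages are available from the shell:

```
chromage simulate --seed 7 --out-dir run/
chromage date --out-dir run/
chromage classify-origin --out-dir run/
chromage call-expression --out-dir run/
chromage compose --out-dir run/
chromage report --out-dir run/
```

Every stage appends to `run/manifest.json` (config, seed, sha256 digests
of outputs); reruns with the same seed reproduce identical digests.

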