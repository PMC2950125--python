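# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not establish.

## Species ladder and branch ages

The focal lineage is modelled as a *ladder*: every speciation split on
the root-to-focal path peels off exactly one outgroup clade (which may
contain several species, e.g. a mouse+rat clade joining at one split).
Non-ladder topologies are rejected at load time. Branch `i` is the
lineage interval between splits `i−1` and `i`; branch `B` (the youngest)
is focal-species-specific.

The default ladder has 13 branches (indices 0–12) with single-species
outgroups from teleost fish to chimpanzee. Split ages follow standard
vertebrate divergence times (fish −450, frog −370, chicken −310,
platypus −180, opossum −160, afrotherians −130, laurasiatherians −90,
rodents −75, marmoset −45, macaque −30, orangutan −15, chimp −6 myr).
Each branch is plotted/fitted at its interval midpoint (branch 12:
−3 myr for the −6..0 interval); branch 0 predates the oldest split and
its midpoint is conventionally pinned at −500 myr. These ages are a
package construction — any ladder can be supplied as Newick plus a
branch-age TSV.

## Parsimony dating

Ortholog evidence per gene is one call per species in
{present, absent, missing}. Within a multi-species outgroup clade a
single present call marks the clade present (the gene predates its
radiation); all-absent marks it absent; otherwise missing.

Dating assumes a single origination event and unit costs for gains and
losses. Scoring every candidate origin branch, the optimum is the split
of the most ancestral present outgroup ("presence beyond intervening
absences wins": those absences become losses). Cost ties are resolved
toward the *older* branch, so a run of missing calls immediately beyond
the most ancestral presence extends the assignment older
(`gap_inferred`); an absent call crownward of a present one marks
`conflict_resolved`. All-absent evidence dates a gene to the
focal-specific branch; all-missing evidence is unassignable.

Two consequences are load-bearing and tested: (i) the fast rule equals
exhaustive single-origin scoring over all 3^S call patterns for small
ladders; (ii) under random missing-call dropout of staircase evidence,
every dating error points toward an older branch — never younger — which
makes the dating conservative for young-gene identification. One caveat:
on loss-heavy conflict patterns (a present call older than an absence
that is itself older than another present), blanking the oldest present
call can legitimately move the optimum younger; the
"missing-never-younger" guarantee therefore applies to single-origin-
consistent evidence (what synteny pipelines emit), not to arbitrary
patterns.

## Origin mechanisms

Young genes are classified from paralog hits (e-value ≤ 1e-6) and intron
configuration in the aligned interval: a retrogene's best-hit parent
carries ≥ 1 intron inside its aligned span while the child has none in
its own; any other hit configuration is a DNA-level duplicate; no
qualifying hit and no annotated paralog means de novo. Best hit = lowest
e-value, ties broken by longer aligned span then lexical parent id.
Introns count only when *fully contained* in the aligned interval — the
conservative reading; partially overlapping introns are ignored.
Coordinates are 0-based half-open bp throughout.

## Expression calls

*Presence* is a strict consensus: present only if detected in every
replicate, absent only if detected in none, ambiguous otherwise;
ambiguous genes are excluded from expressed proportions
(present/(present+absent)). Detection compares gene-level signal to a
background pool with a one-sided Wilcoxon rank-sum test; p-values are
BH-adjusted jointly across genes and replicate groups with a q cutoff of
0.01.

*Sex bias* is gonad-vs-gonad (testis vs ovary) on log2(x+1) intensities,
labelled male/female rather than testis/ovary because gonadal bias
dominates sex-biased expression genome-wide. The test is a shrinkage
*t*: the pooled per-gene variance (df = n₁+n₂−2) is replaced by
`(d₀·s̄² + df·s_g²)/(d₀ + df)` with prior weight `d₀ = 4` residual-df
units toward the genome-wide mean variance, and referred to `df + d₀`
degrees of freedom. This stabilises small-replicate calls the way
moderated-t approaches do, without empirical-Bayes hyperparameter
fitting; with zero residual variance the statistic is ±∞ for unequal
means (perfect separation) and 0 otherwise. Calls use BH-adjusted p at
FDR 0.05; fewer than two replicates per gonad yields `not_assayed`.
Multiple-testing control is Benjamini–Hochberg throughout (a q-value
estimator would be less conservative but adds a tuning step).

## Composition and enrichment

Per-branch X share is reported only for branches with ≥ 1 gain (empty
branches are undefined, not 0). Male-bias age curves drop
(branch × class) points with fewer than 5 assayed genes; the summary
regression of proportion on midpoint age weights points by √(assayed
genes). Contingency tests are Pearson chi-square without continuity
correction (2×3 bias tables, 2×2 presence tables) or Fisher exact
(2×2), all delegated to one statistics module. Fisher's two-sided p uses
the minimum-likelihood summation convention; tables with a zero margin
are uninformative and return p = 1.

The enrichment heatmap scores each (branch, tissue) cell as
−log10(Fisher p), signed positive when the X-linked expressed proportion
exceeds the autosomal one, clamped symmetrically at ±8 so a single
astronomically small p cannot dominate the colour scale. Tissue order
comes from average-linkage clustering on Euclidean distance between
score columns and is presentational only.

Strata association tests whether young genes concentrate in the young
strata of the X (4–5) versus the old strata (1–3) with a one-sided
Fisher test; PAR and undefined-stratum genes are excluded.

## Divergence and the decay model

Relative abundance normalises a gene's per-tissue intensities to sum
to 1 (all-zero genes are flagged undefined). Divergence is the sum of
squared RA differences — deliberately *not* square-rooted, so D ∈ [0, 2]
for probability vectors; the name "distance" is kept loosely.

The decay model `f(t) = N(e^{rt}(1−d)+d)` is fitted by weighted
nonlinear least squares: weights are per-branch gene counts, equivalent
to Gaussian maximum likelihood with variance ∝ 1/count. Constraints
N > 0, r ≥ 0, 0 ≤ d ≤ 1. Initialisation: N₀ = proportion at the youngest
branch, d₀ = oldest/youngest ratio clipped to [0.01, 0.99], r₀ = 0.05
per myr, followed by 19 jittered restarts (log-normal on N₀ and r₀,
normal on d₀) from a fixed seed; the best converged solution is kept and
non-convergence across all starts raises. Noiseless inputs are recovered
to 1e-6 in all three parameters; on binomially noisy inputs at 300 genes
per branch the sampling spread of the recovered N is σ ≈ 0.05, which is
the information floor of that design rather than an optimiser artefact
(a binomial ML refit gives the same spread).

## What the generator emulates — and what it does not

`SimulationConfig` defaults define the study conditions: ~19,900 genes
across 13 branches (most predating the vertebrate radiation, ~1,800
young), an X share of gains of 3% outside two peak intervals (branches
5–7 and 11–12) reaching 8–14% inside them, X-linked male-bias
proportions following the decay curve `N=0.74, r=0.08, d=0.42` against a
flat 30% autosomal level, a 15% female-bias rate, a DNA-duplicate–
dominated mechanism mixture (80/12/8), MSCI silencing of old X genes in
meiotic/post-meiotic cells (probability 0.40) with young X genes instead
present post-meiotically at 0.70, log-normal intensities (log2 sd 0.35)
over 4 gonadal and 2 stage replicates, between-species log2 drift of 0.3
inflated to 1.2 for young X genes in spermatids, and 10% ortholog-call
dropout. Strata placement is weakly age-associated (old X genes fall in
strata 1–3 with probability 0.75, young in 4–5 with 0.55, 2% PAR).

The generator reproduces marginal structure, not biology: intensities
are exchangeable log-normals without probe effects, array batch
structure, cross-hybridisation, or correlated gene modules; ortholog
dropout is independent per call rather than clustered in telomeric or
repeat-rich regions; and true bias labels are drawn independently per
gene. Passing round-trip tests therefore demonstrates that the
*inference machinery* is correct and directionally calibrated under the
assumed noise model — it does not validate the biological conclusions on
real arrays, where normalisation and probe annotation dominate error.

## Problem sizes

The default test suite simulates genomes of ~900–20,000 genes depending
on what a test needs to resolve: full-size (~20,000) for binomial-bound
checks on the two-peak curve, ~2,600 for expression round-trips, and
toy 4–7-species ladders for exhaustive parsimony enumeration. The
acceptance script fits 11 branch points at 300 genes per branch.

## Known limitations

* Ladder-only trees; reticulate or non-ladder topologies are rejected,
  not approximated.
* The shrinkage t is a fixed-prior approximation to moderated
  empirical-Bayes tests; borderline calls near the FDR threshold can
  differ from such tools.
* The spermatogenesis per-stage divergence machinery reports mean D per
  stage; absolute percentage "divergence levels" depend on a
  normalisation convention that is not standardised here.
* Fisher enumeration is exact; for very large 2×2 tables the
  hypergeometric tail from scipy is used as-is (no mid-p option).
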