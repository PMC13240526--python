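# Methods

## Model and procedure

The pipeline characterizes where a small set of *seed genes* (by default the
six CCN matricellular proteins) sits inside the co-expression and
protein-interaction structure of a differentiating culture, and how much of
that neighborhood is conserved between species.

**Co-expression modules.** For a genes × samples matrix of normalized
expression, the signed-hybrid adjacency is `a_ij = cor(i,j)^β` when the
Pearson correlation is positive and 0 otherwise, so anti-correlated genes are
never connected. Zero-variance genes are dropped (correlation undefined)
with a logged warning. The topological overlap

```
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
k_i = Σ_{u≠i} a_iu
```

rewards shared neighbors; modules are found by average-linkage clustering of
`1 − TOM` with a *static* cut at `cut_height_frac` (default 0.98) of the
maximum merge height. Clusters below `min_module_size` (default 30) are
pooled into "grey" (unassigned). Module labels follow the conventional color
sequence in decreasing size order (largest = turquoise); size ties break on
the lexicographically smallest member gene, which makes labeling
deterministic. The dynamic hybrid tree cut and eigengene-based module
merging of the reference WGCNA implementation are deliberately out of scope:
a static cut is fully reproducible and testable, at the cost of absorbing
some background genes into modules near the cut height (see Limitations).

**Soft power.** When `soft_power` is unset, the smallest candidate (1–20)
whose scale-free topology fit reaches R² ≥ 0.8 is chosen: connectivities are
binned into 10 equal-width bins and log10(frequency) is regressed on
log10(mean connectivity); a candidate qualifies only with ≥ 5 non-empty bins
and a negative slope (a positive slope can produce a high R² on structured
data without any scale-free interpretation). If no candidate qualifies —
typical for strongly modular data, which is not scale-free — the declared
fallback β = 9 is used and flagged. Planted-module fixtures always take this
fallback path; that is expected behavior, not an error.

**Eigengenes and trait correlation.** A module eigengene is the first right
singular vector of the per-gene z-scored module submatrix (unit norm,
one value per sample), sign-oriented so its correlation with the module's
mean profile is nonnegative — this makes results independent of gene-row
order. `variance_explained` is the first squared singular value over the
total. Eigengenes are correlated with numeric culture day (Pearson); the
two-sided p-value uses `t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom,
which the test suite checks against a 10⁵-shuffle permutation oracle.

**Seed networks.** PPI edges come from STRING-export TSVs; the score dialect
(0–1000 vs 0–1) is auto-detected and the confidence threshold (default 0.4)
is applied *inclusively*. Within each trait-significant module (trait p <
0.05) containing at least one seed gene, the network is the depth-1
neighborhood of the module's seeds in the module-induced PPI subgraph, with
all induced edges retained (neighbor–neighbor edges included, not a star).
Per-module networks are merged by node/edge union; provenance records which
module(s) each node entered from; degree is recomputed, unweighted, on the
merged graph (per-module degree is available by running the stages
separately). Seeds absent from the PPI file — e.g. a species lacking an
annotated ortholog — are retained as isolated flagged nodes rather than
aborting the run.

**Stability.** Bootstrap stability reruns module detection on `n_iter`
(default 10) uniform subsamples of ⌊0.8·n⌋ samples drawn *without*
replacement ("80% of samples" is read as subsampling, not classical
with-replacement bootstrap) and scores each partition against the full-data
reference with a best-match, size-weighted Jaccard over non-grey reference
modules. Grey genes are excluded — unassigned genes would otherwise dominate
every union. Leave-out retention removes ⌊0.1·n⌋ samples once, reruns the
entire module → seed-network chain and reports the fraction of reference
seed-network genes recovered. Because these single-number summaries depend
on the matching rule, every report embeds the declared metric definitions.

**Conservation.** One-to-one ortholog filtering keeps a pair iff its A-gene
occurs exactly once in the A column and its B-gene exactly once in the B
column, yielding a bijection (the reciprocal-uniqueness property of
bidirectional best hits). Symbols are compared case-insensitively after
whitespace stripping (Ccn1 vs CCN1), with display case preserved. For a
category with gene sets A and B, `index_A = |shared|/(|shared|+|A-only|)`,
`index_B` analogous, `jaccard = |shared|/|union|`; the three parts are
disjoint and exhaustive, and jaccard ≤ min(index_A, index_B) always. The
homologous network keeps ortholog pairs present in both species' seed
networks (named by species-A symbols) and retains an edge present in either
induced subgraph — gene content is intersected, edges are unioned, with the
supporting species recorded per edge. Three-way Venn placement translates
all genes to a canonical namespace through the pairwise maps, after checking
the maps for mutual consistency (inconsistent triples are logged and
excluded).

**Enrichment.** Over-representation uses the upper-tail hypergeometric
probability P(X ≥ k) with universe N (defaulting to all genes in the
species' expression matrix — the standard ORA choice), term size K, query
size n; zero-overlap terms are omitted and Benjamini–Hochberg adjustment
runs across all tested terms (delegated to statsmodels; the step-up formula
itself is an oracle in the test suite). Significant terms (q < 0.05) roll up
into five principal categories via an ordered, user-editable keyword rule
list (first match wins; unmatched terms stay "unclassified"). The shipped
default keyword list covers the common GO/KEGG vocabulary of each category
but is a configuration file, not a claim about any particular annotation
release.

**Single cell.** QC removes cells with detected genes strictly below
`min_genes` or strictly above `max_genes`, or mitochondrial count fraction
strictly above `max_mito` (a literal reading of "more than X" — boundary
cells are kept), then genes detected in fewer than `min_cells_per_gene`
surviving cells; the order (cells first, then genes) is fixed and the filter
is idempotent. Two named profiles ship: `hipsc` (200, 7000, 5%, 3) and
`embryonic_limb` (200, 6000, 10%, 1). Normalization scales each cell to the
median total count and applies log1p. The recovery-curve activity score
ranks genes per cell by decreasing expression (ties broken lexicographically
for cross-platform determinism), takes the top T = ⌈top_frac·n⌉ ranks
(top_frac default 0.05, the cited convention, configurable) and integrates
the cumulative set-gene hits, normalized by the maximum achievable sum
Σ_{t≤T} min(t, m) so the best case is exactly 1. The rank-sum alternative
clips set-gene ranks at `max_rank` (default 1500) and maps the Mann–Whitney
U statistic to [0, 1]. Ligand–receptor strength is deliberately simple —
mean ligand expression in the sender population × mean receptor expression
in the receiver population — a declared simplification of probabilistic
communication frameworks, adequate for ranking planted interactions. Cell
cluster labels, embeddings and batch integration are *inputs*, not
computations.

## Synthetic data generator

The generator emulates the study design the pipeline targets: three species
profiled over a chondrogenic time course (days 1, 3, 6, 10 × 3 replicates)
with planted co-expressed modules. Module latent profiles are low-order
functions of day — monotone increase, monotone decline, and a transient
quadratic — standardized across samples; a member gene is
`loading · trait_effect · latent + N(0, noise_sd)` with loadings uniform in
[0.8, 1.2], and background genes are pure noise. Seed genes (human CCN1–6,
mouse Ccn1–6, chicken CCN1–5 — the chicken genome lacks CCN6) occupy the
first planted module. PPI graphs are Bernoulli with denser within-module
edges (defaults 0.8 within / 0.05 between, scores uniform in [0.4, 1]).
Ortholog tables assign each base gene one2one / one2many / species-specific
status at requested fractions (defaults 0.7 / 0.15 / rest); one-to-many
genes are emitted as paired double rows so strict filtering removes them.
Single-cell counts are negative-binomial (fixed dispersion 2) over ~300
genes and 500 cells in four populations × three time points, with one
population's 20-gene "ccn_network" set multiplied by exp(activity_shift)
(default shift 2), a CCN1 ligand elevated in mesenchymal senders, an ITGB1
receptor in chondrocyte receivers, mitochondrial genes drawing per-cell
fractions from Beta(2, 38) (mean 5%), and three sentinel cells that violate
each QC rule so filters are always exercised. Every generator is a pure
function of its parameters and seed.

What the generator does **not** emulate: batch effects, sequencing error,
library-composition biases, dropout structure beyond NB sampling, gene-gene
correlation inside the background, or realistic pathway topology in the PPI
graphs. Passing tests therefore demonstrate algorithmic correctness and
recoverability of planted structure under the stated noise, not performance
on real accession data, whose module sizes, annotation coverage and
stability values (e.g. bootstrap Jaccard near 0.4–0.5 on real time courses)
differ substantially.

## Problem sizes and numerical choices

The standard study conditions used by the test suite and
`scripts/acceptance.py`: 3 species × (96 genes × 12 samples) bulk matrices
(3 planted modules of 30, noise_sd 0.3, trait_effect 1.0), PPI graphs of
~100 nodes, 500-cell × 312-gene count matrices. These sizes keep a full
pipeline run in seconds while leaving every statistic away from degenerate
regimes. The signal-vs-noise stability comparison runs both arms at
min_module_size = 3 so the pure-noise arm yields a non-degenerate reference
partition (at the default 30 a pure-noise reference is all grey and the
Jaccard is undefined by contract; an all-grey reference in the acceptance
script is reported as stability 0 — no reproducible module structure).

Numerical conventions: inclusive threshold comparisons at STRING and QC
boundaries as documented above; degree ties in hub tables break
alphabetically; eigengene and PCA component signs are pinned (nonnegative
correlation with the mean profile, nonnegative loading of the
lexicographically first gene, respectively); correlations use population
(ddof 0) standard deviations; all randomness flows from explicit
`numpy.random.default_rng` seeds, with one master seed split via
`SeedSequence` in the CLI and acceptance script.

## Known limitations

- The static tree cut can attach background genes to strong modules near the
  cut height; module *content* recovery is exact on the standard fixture,
  but specificity against background genes is weaker than a dynamic cut
  would give.
- On noiseless fixtures, subsamples that drop a whole timepoint can make the
  decline and transient-peak latent profiles nearly collinear, occasionally
  merging those modules in a bootstrap iteration (visible as isolated 2/3
  Jaccard entries).
- The best-match partition Jaccard is one of several defensible matching
  rules; reports embed the definition so numbers are comparable only within
  it.
- The ligand–receptor score ignores receptor complexes, downstream signaling
  evidence and expression thresholds.
- The enrichment universe default (all expressed genes) is configurable but
  never inferred; genome-wide universes give systematically smaller
  p-values.
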