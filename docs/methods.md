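# Methods

## Model and procedure

A gene is *multifunctional* when it carries annotations to two ontology
terms that are of comparable specificity and demonstrably distinct. The
operational definition has three ingredients.

**Specificity levels.** With true-path-propagated counts (an annotation to
a term implies annotation to every ancestor), the level set
*T_N* = {t : N ≤ count(t) < 2N and every descendant of t counts < N}.
The lower bound and the descendant condition are the classic "informative
terms" construction; the 2N upper bound additionally rejects general terms
whose children all happen to be small. Terms without descendants qualify
vacuously, and the namespace root is treated like any other term (in
practice it always fails the 2N bound). Counts are propagated by default; a
`propagate=False` escape hatch exists for sensitivity analysis only, since
direct-only counting breaks the monotonicity the selection logic assumes.

**Distinct pairs.** Within one level (never across levels), an unordered
term pair survives when (i) its only common ancestor is the namespace root,
with neither term ancestral to the other — implemented as a common-ancestor
set condition, which is equivalent to "least common ancestor is the root"
on a DAG and remains well-defined with multiple common ancestors; (ii) the
terms share no common descendant; (iii) the overlap of their propagated
gene sets is not larger than chance expects under an upper-tail
hypergeometric test at raw p ≥ α (default α = 0.1; per-pair p-values are
deliberately uncorrected — the filter asks "is this single pair suspicious",
not "which of all pairs are"). The co-annotation universe is the set of all
genes annotated in the namespace.

**Union over levels.** Levels run over N = 10, 20, …, M (default M = 120,
increment 10). A gene co-annotated by any surviving pair at any level is
called; its evidence records every witnessing (N, term1, term2) with the
overlap and p-value. The background is every gene annotated by at least one
selected term at any level; "other annotated genes" in comparisons means
background minus called. Output ordering is fully deterministic (genes
lexicographic, evidence by (N, term1, term2)), so reruns are byte-identical.

Membership of a gene in a pair's two term sets uses propagated sets,
consistent with the counting; the stricter alternative (direct annotation
to both paired terms) would only shrink the call set and is not exposed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| M | 120 | largest specificity threshold; higher M admits more general terms |
| increment | 10 | grid step for N |
| α | 0.1 | co-annotation filter threshold (raw hypergeometric p) |
| evidence whitelist | 14 codes | EXP, IDA, IMP, IGI, IEP, ISS, ISO, ISA, ISM, IGC, IBA, IC, TAS, NAS; `--strict-evidence` restricts to EXP, IDA, IMP, IEP, IC, TAS |
| traversal relations | is_a, part_of | ontology edges used for propagation and reachability |
| hub cap | 200 | networks: iterative removal of the highest-degree node above the cap |

Annotations with the `NOT` qualifier are always discarded; annotations to
obsolete or unknown terms are skipped with a warning (obsolete terms are
retained as records for diagnostics but carry no traversal edges).

## Statistics

*Mann–Whitney U* is two-sided; exact enumeration when n₁·n₂ ≤ 400 and the
pooled sample is tie-free, otherwise a tie- and continuity-corrected normal
approximation (the two paths agree to <0.01 at n₁ = n₂ = 15; identical
samples give exactly p = 1 on both). Direction is reported separately from
the p-value.

*Partial Spearman* is the Pearson correlation of rank residuals after
linear regression of the ranks of each variable on the ranks of the
control — the standard definition, cross-checked in the test suite against
an independent implementation.

*Matched resampling* draws candidate samples bin-matched to the target
group's covariate distribution: quantile bins of the target distribution
(10 by default), or exact-value bins when the covariate takes at most that
many integer values (isoform counts, small discrete covariates). Draws are
with replacement within bins, so one candidate per occupied bin suffices;
an occupied target bin with no candidate is a hard error. The default
statistic is the median (mean/proportion available) and the default
alternative is upper-tailed, since the questions posed are of the form "is
the target group's value still higher after matching".

*Empirical p-values* are (exceedances + 1)/(trials + 1); 1000 trials with
zero exceedances report p ≈ 9.99e-4, i.e. "< 1e-3".

*Ortholog permutation test*: multifunctional/other labels are shuffled
independently within each organism, restricted to genes that appear in the
ortholog pair list, preserving per-organism label counts; the orthology map
itself is fixed. Each gene receives one label per trial, so genes in many
pairs stay internally consistent. For a one-to-one map the null expectation
is n_pairs · f_A · f_B, which the test suite checks the simulated null
against.

*Betweenness* is unnormalized (only rank comparisons between gene groups
consume it; normalization by pair count is rank-invariant). *Participation*
of a degree-0 node is defined as 0 rather than NaN so rank statistics stay
total. The greedy modularity clustering (CNM, via networkx) is a
deterministic baseline; production analyses are expected to supply an
external partition (e.g. SPICi output) through the cluster TSV interface —
the `seed` argument of `greedy_cluster` exists for interface stability and
is unused.

## Synthetic fixtures: what they emulate and what they do not

The generators define the study conditions for all tests. The ontology
generator emits a single root over disjoint branch subtrees (optional
within-branch cross-links), so cross-branch term pairs satisfy the
root-only-ancestor condition by construction. The annotation generator
plants, at its defaults (300 genes, 25 planted multifunctional, 10
background genes per leaf, N-grid 10…120):

* background genes annotated to exactly one leaf — their propagated terms
  lie on a single root path, so no distinct pair can ever co-annotate them;
* planted multifunctional genes annotated to balanced, gene-specific
  cross-branch leaf pairs, with loads capped so every usable leaf count
  stays within one specificity window [10, 20) and no planted pair's
  overlap becomes co-annotation-enriched;
* optionally a decoy pair in two reserved branches co-annotated by a block
  of 30 shared genes, enriched far beyond chance at every level where the
  decoy terms or their branch ancestors are selected — exercising the
  hypergeometric filter end to end;
* filler genes annotated to the root only, fixing the universe size without
  touching selection.

Because of this construction, recovery of the planted set with precision =
recall = 1 is a structural property at the default parameters, not a
statistical accident, and the planted/decoy configurations were chosen once
from the count arithmetic above. What the fixtures deliberately do **not**
emulate: the scale-free, deeply multi-parent topology of the real Gene
Ontology; annotation biases correlated with study effort; noisy or
conflicting evidence codes; many-to-many ortholog families (the generator
is one-to-one; the counting and permutation code handle many-to-many
inputs). Passing tests therefore demonstrate correctness of the method's
logic, not robustness to real-data pathologies.

The orthology generator with excess = 1 assigns labels uniformly at random
(the calibration null); with excess > 1 it plants exactly
round(excess · n · f_A · f_B) both-multifunctional pairs while preserving
marginal label counts. The network generator is a planted-partition model;
the feature generator adds configurable location shifts to standard normal
noise.

## Numerical and design choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, …)`; the
  test suite checks them against exact rational enumeration for universes
  ≤ 12 (to 1e-12) and an independent big-integer implementation elsewhere.
* Term selection has no tie-breaking to speak of; pair filtering and
  evidence are computed over lexicographically sorted terms so output
  ordering never depends on hash or insertion order.
* Hub removal recomputes degrees each iteration and removes a single
  highest-degree node per iteration, ties broken lexicographically by id;
  the operation is idempotent.
* Degenerate inputs raise informative errors: empty annotation sets, a
  grid that selects no terms (the error reports the top term counts),
  constant vectors in rank correlations, empty groups in comparisons,
  unmatched covariate bins.
* Problem sizes in the test suite (≤ 60-term ontologies, ≤ 300 genes,
  ≤ 500-node networks, 199–1000 permutation trials, 200-replicate
  calibration loops) were chosen as the smallest sizes at which the checked
  properties are non-trivial; the full suite runs in well under a minute.

## Known limitations

* Only the root-only-LCA notion of term distinctness is implemented; no
  graded semantic-similarity threshold is available.
* The background definition ties "other annotated genes" to the selected
  term union, so it shifts with M and α — intentionally, as comparisons
  should condition on the same annotation depth.
* GAF parsing keys genes on the database object id (column 2); isoform-level
  subjects (column 17) are not collapsed or expanded.
* The co-annotation universe is the annotated-gene set of the namespace;
  other universes (e.g. whole proteome) must be imposed upstream.
* No multiple-testing correction is applied anywhere by design; all
  reported p-values are raw.
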