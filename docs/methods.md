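# Methods

This note documents the models and procedures implemented in `pathnet`,
the parameters that matter, the synthetic data the package tests itself
on, and the numerical and design choices a user auditing results should
know about.

## Pipeline model

The package builds a weighted graph whose vertices are curated pathway
gene sets and whose edge weights are semantic similarities between the
pathways' minimal enriched GO Biological Process profiles.  The stages
run strictly in this order: curation → annotation filtering/propagation →
enrichment → profile minimization → proportional set cover → similarity →
threshold scan → pruning → structure statistics → disease mapping →
clustering tests.  Each stage is a pure function of its inputs and the
configuration; a single master seed derives all stage seeds, so a run is
byte-reproducible.

### Curation

Duplicates are groups of pathways with identical gene sets; the
lexicographically smallest id survives, making the choice independent of
input order and provenance.  Name filtering is case-insensitive substring
matching against per-category term lists (disease / drug / addiction).
The shipped default lists cover the standard categories but are
explicitly a starting point: for real collections the list is data, not
algorithm, and should be supplied by the user (`load_name_filters`).
Loose substring matching is deliberate — drug pathway names rarely appear
as clean word-boundary tokens.

### Annotations

Evidence is binary: `IEA` versus everything else.  IEA is the only
evidence class excluded because it is the only class without curator
review; finer gradations (e.g. treating RCA separately) are out of scope
and would need a one-line change in `annotations.load_gaf`.  Ancestor
propagation follows the true-path rule over both `is_a` and `part_of`,
matching standard GO practice.  Propagation is idempotent and never
removes a (gene, term) pair; after it, the carrier set of a parent term
is always a superset of each child's.

### Enrichment

The test is the one-sided upper hypergeometric tail P(X ≥ k) for an
overlap of k query genes among K background carriers (equivalent to the
one-sided Fisher exact test).  Two different multiplicity conventions are
used on purpose:

* **GO profiles**: Benjamini–Hochberg adjustment within each pathway's
  test family, threshold α = 0.01 — the convention of the standard
  over-representation tools this stage mirrors.
* **Disease mapping**: raw p < 0.01, no correction — disease–pathway
  association is a screening step whose hits feed a second, explicitly
  permutation-style test (the module-clustering KS test), so the
  correction burden sits there.

The background universe is the union of annotated genes over all curated
pathways.  With it fixed, restricting a term's carriers to the background
before testing makes results invariant to annotations outside the
universe.

### Profile minimization and the proportional set cover

Both reductions are greedy set covers with full determinism (every tie
ends at a lexicographic comparison).

`minimize_profile` selects, among terms still covering uncovered genes,
the most significant (smallest p; ties by larger gain, then term id), and
stops when no candidate adds coverage.  Genes carried by no enriched term
are excluded from the cover target — otherwise small pathways with partly
unannotatable genes would never terminate.  A final pass then discards
terms that ended up redundant, least significant first, so the output is
irredundant: every retained term covers a gene no other retained term
covers.  This discard step is part of the method's contract ("terms
describing the same genes at lower significance are discarded"), not an
optimization.

`proportional_set_cover` selects pathways by uncovered-gene count,
breaking ties toward a target size — by default the median candidate size,
computed from the data rather than hardcoded — and stops at a coverage
fraction (default 99.95 %).  Stopping just short of 100 % is what allows
enormous catch-all pathways to drop out: their only marginal contribution
is a handful of residual genes.  The same irredundancy post-pass applies,
in reverse selection order, and never lowers the achieved coverage.

### Semantic similarity

Wang S-values decay multiplicatively along child→parent edges with
weights 0.8 (`is_a`) and 0.6 (`part_of`) — the canonical defaults of the
measure, of which the method only fixes the ordering (is_a heavier).
With multiple paths the maximum product wins; parallel is_a/part_of edges
between the same pair collapse to the heavier weight.  Resnik similarity
is the information content −log p(t) of the most informative common
ancestor, where p(t) is the annotated-gene fraction after propagation;
scores are divided by the corpus maximum IC so both measures share the
[0, 1] edge scale and one threshold scan applies to either.  Common
ancestors include the compared terms themselves, making self-similarity
well-defined and maximal.  Terms carried by no annotated gene have no
defined p and cannot be compared under Resnik; they raise rather than
silently scoring 0.

Set aggregation: the pairwise average (mean over the full cross product)
and the best-match average.  BMA dominates the pairwise average
everywhere and assigns 1 to identical profiles; that behavior (checked
exactly in the tests: identical two-term profiles with mutually
dissimilar terms score 0.5 pairwise but 1.0 BMA) is why BMA over Wang
similarities is the default edge weight.  Term similarities are cached
symmetrically; results are independent of evaluation order.

### Threshold scan and network statistics

Candidate thresholds are the even grid k/(n+1), k = 1..n (default
n = 50), strictly inside (0, 1).  The chosen threshold maximizes
nodeFrac − edgeFrac, where nodeFrac counts nodes keeping at least one
edge.  Ties break toward the larger threshold, with one refinement: an
equally scoring threshold that empties the network entirely never beats
one that retains nodes (this matters only in the degenerate all-equal-
weights case).  Pruning keeps all nodes; isolated ones are flagged, not
dropped.

The clustering coefficient is the Watts–Strogatz average of local
coefficients with degree-<2 nodes contributing 0 (the common
network-viewer convention).  The null model is double-edge-swap
randomization (10·|E| swaps), which preserves the degree sequence
exactly.  The power-law fit is the Clauset–Shalizi–Newman discrete MLE
with KS-minimizing xmin, via igraph's plfit; its goodness-of-fit p is
simulation-based, so the implementation pins igraph's RNG to make runs
reproducible.  At the standard fixture's network size (tens of nodes)
this test has essentially no power, so the pipeline reports the fit
without drawing a conclusion from it; on networks of several hundred
nodes and up the p-value is meaningful.

### Disease modules

Distances are unweighted hop counts on the pruned graph; with
similarity-weighted edges there is no canonical similarity→distance
conversion, and integer hops keep the distributions directly comparable.
Pairs split across components are excluded from the distribution but
counted and reported, so the choice is auditable.  The null is 100
uniform samples of equal-size node sets, pooled; the test is a two-sample
KS of observed vs pooled null, reported with the direction flag
(observed mean below null mean = clustering).  A one-sample test against
a parametric reference was rejected because no reference distribution for
shortest paths on an arbitrary graph exists in closed form.

A calibration caveat that holds for this design generally, not just here:
the path lengths within one node set share nodes and are therefore
dependent, so the KS p-values are approximate.  Resampling whole null
node sets shows a type-I rate at the 0.01 level of roughly 2–4× nominal
on the standard fixture, while drawing observed values iid from the
pooled null (independent data, but with integer ties) is conservative.
The planted-disease effects the method is used to detect are orders of
magnitude stronger (p ≤ 10⁻⁴ typical), so the approximation does not
affect the qualitative conclusions; a user needing exact per-disease
error control should permute at the node-set level and compare KS
statistics rather than rely on the KS p directly.

## Synthetic data: what it emulates, and what it does not

The generator (`pathnet.synthetic`) produces an OBO ontology, GAF
annotations, a GMT pathway collection, a disease gene table, and
ground-truth TSVs, all as pure functions of (config, seed).

* **Ontology**: a rooted DAG whose 8 first-level branches act as
  functional themes; random tree growth plus extra parents (15 % of
  terms), ~30 % of which cross branches — the cross-process term sharing
  real ontologies exhibit.  15 % of edges are `part_of`.
* **Annotations**: each gene has a deterministic *home term*; its direct
  annotations concentrate in the radius-2 neighborhood of that term
  (90 % locality), with overdispersed counts (negative binomial, mean
  8.2, sd 9.2).  4 % of genes are unannotated and 7.6 % IEA-only, so the
  evidence filter and coverage filter both fire.
* **Pathways**: each nucleates around a *seed term* and samples genes
  homed in the seed's subtree — after propagation all of them carry the
  seed term, giving the coherent enrichment signal real pathways show.
  Larger pathways span a secondary locality, sometimes in another branch
  (cross-talk), which is what knits the pruned network into large
  components.  Sizes are lognormal (median 23, σ = 1.2, long-tailed);
  15 % of draws come from a shared hub-gene pool (membership inflation);
  10 % of pathways are exact duplicates; 9 carry disease/drug/addiction
  names; 2 are below the annotation minimum.
* **Diseases**: 10 planted diseases draw 30 genes from the theme-homed
  core shared by 4–9 gene-overlapping source pathways of one theme;
  10 null diseases draw genes uniformly.  Some planted names match the
  cancer term list so name-based system selection is exercised.

The standard fixture ("std-v1", seed 17: 160 terms, 1000 genes, ~220 raw
pathways) is sized so that the full pipeline runs in ~15 s on one CPU
while enrichment and the disease statistics retain power; those problem
sizes are the package's chosen study conditions for all self-tests.

What passing on this fixture shows: the machinery is correct (verified
against brute-force oracles), calibrated under its own null, and able to
recover planted functional structure end to end.  What it does not show:
performance on real CPDB/GO/HPO-scale data, where identifier mapping,
annotation biases, shallow-vs-deep ontology regions, and far larger
multiplicity burdens all matter; the fixture's themes are also cleaner
than real functional overlap.  Real-data headline numbers from the
literature (network of ~1000 pathways, threshold ≈ 0.56, clustering
≈ 0.59) depend on specific database releases and are not reproduced at
this scale.

## Degenerate inputs and numerical notes

* All greedy traces, similarity matrices and output files are
  deterministic; ties everywhere end at a lexicographic comparison.
* `threshold_scan` requires at least one positive weight; all-zero
  similarity is an error, not an empty network.
* `power_law_test` refuses degree sequences that are all equal or have
  fewer than 10 positive entries.
* `ks_cluster_test` refuses empty path multisets; diseases mapping to
  fewer than 2 nodes are skipped (and therefore never counted as
  clustered).
* BH adjustment requires p ∈ (0, 1]; zeros (possible only through
  underflow) are rejected loudly rather than adjusted.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, exact for
  the integer sizes used here; tests verify them against direct
  summation.
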