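# Methods

## Ontology model

The ontology is a rooted directed acyclic graph over phenotype terms in
which edges are `is_a` (subsumption) relations pointing child → parent.
Only `is_a` relations are used; `part_of` and other relations in an OBO
file are ignored, since subsumption is what licenses the true-path rule
the information-content model rests on. Loading validates acyclicity and
single-rootedness and fails loudly otherwise. Obsolete terms are kept for
id lookup (so stale inputs produce a precise error) but carry no edges and
are excluded from every DAG operation; `alt_id`s resolve to their primary
term at annotation-load time.

Annotation corpora map entities — diseases or genes — to term sets.
Propagation closes each set under ancestors (an entity annotated to a
term is implicitly annotated to everything the term subsumes it under);
it is idempotent and leaves the direct sets untouched. Which corpus
drives IC is a parameter: the disease corpus is the default when both are
available, and gene-based IC is obtained simply by passing the gene
corpus.

## Information content and its conventions

IC(t) = −log(|D_t|/|D|) with |D_t| counted after propagation. Two
conventions make IC a total function:

* **Log base** — natural log by default, base 2 selectable. Lin and
  Schlicker are ratios of ICs and therefore base-invariant; Resnik and
  the Jiang–Conrath *distance* are in IC units and rescale by 1/ln 2
  under base 2, which also changes the JC similarity 1/(dist+1). The base
  is recorded on every similarity matrix.
* **Never-annotated terms** — |D_t| is clamped to 1, assigning such terms
  the maximum observed specificity (−log(1/|D|)) rather than an infinite
  IC. This keeps all five measures finite everywhere.

The MICA maximizes IC over the *inclusive* common ancestor set (a term is
its own ancestor for this purpose, so MICA(t, t) = t). Ties on IC break
to the lexicographically smallest id, making every downstream score
deterministic.

## Term measures

Resnik, Lin, Schlicker and Jiang–Conrath follow their standard
IC/MICA definitions (see README table). Conventions: Lin returns 0 when
IC(a)+IC(b) = 0 (both terms are the root — no shared information);
Resnik is reported raw, with an optional max-IC normalization flag for
network-threshold comparability, off by default.

The path-constrained measure (`phenosim`) is
IC(MICA)/(1 + L(a, b)), where L is the minimum, over common ancestors
achieving the maximal IC, of the shortest-path edge count from each term
up to that ancestor. It equals Resnik at L = 0 (identical terms) and is
strictly smaller otherwise, penalizing pairs whose shared ancestor —
although informative — sits many levels away. The 1/(1+L) form is this
package's concrete choice of path penalty; it is exposed as part of the
measure rather than hidden, and the surrounding constants are keyword
arguments so variants can be substituted without code change.

## Phenotype network and profile denoising

Patient phenotype lists are noisy: clinical records include terms that
are incidental to the underlying condition. The denoising model assumes
the *relevant* terms support each other — they co-occur in gene
annotation sets or sit close together in the ontology — while noise terms
are isolated from the rest of the profile.

The phenotype network has one node per annotated term plus all ancestors.
Edges: every `is_a` edge (weight 1.0, tag `ontology`) and an edge between
any two terms whose direct-annotation entity sets intersect, weighted by
the Jaccard index of those sets (tag `co-annotation`); parallel edges
collapse to the larger weight. Weights and damping are configuration
keys: ontology weight 1.0, damping 0.85, tolerance 1e−10 on the L1
residual, at most 200 power iterations, drop fraction 0.2.

Personalized PageRank restarts uniformly on the profile members present
in the network; dangling (isolated) nodes return their mass to the
restart distribution. The stationary vector is computed by power
iteration and always sums to 1; the test suite checks it against a dense
solve of the stationarity system to 1e−8. Denoising removes the
⌊drop_fraction·|profile|⌋ lowest-scoring profile members, never all of
them. Profile terms absent from the network score 0 and are removed
first. Ties retain the higher-IC (more specific) term, then the
lexicographically smaller id.

## Set similarity, ranking, p-values

Set similarity aggregates a pairwise measure over two term sets; the
default is the symmetric best-match average (BMA), the standard choice
for profile-vs-profile comparison, with `max` and `avg` available. Gene
and disease similarity is set similarity over the entities' *direct*
annotation sets. Ranking scores every candidate (all annotated entities
when no list is given), sorts descending with lexicographic tie-break,
and is a pure function of (query, corpus, config, seed).

The permutation null redraws the query as a uniform random term set of
the same size from the universe of directly annotated terms — the
simplest defensible null, preserving query size but not IC composition
(IC-stratified sampling would be the natural refinement and is left as
future work). The add-one estimator p = (1 + #{null ≥ observed})/(M + 1)
is bounded below by 1/(M+1); M defaults to 1000 in the library (100 in
the CLI for interactive latency). Under the null the p-values are
uniform, which the suite verifies with a KS test at α = 0.01 over 200
replicates of M = 200. Benjamini–Hochberg q-values are attached across
candidates of a ranking.

## Text mapping

The lexicon indexes every active term's name and synonyms after
normalization (case-fold, punctuation → space, whitespace collapse).
Matching is exact after normalization — no stemming, no fuzzy distance —
so behavior is predictable and auditable; fuzzy matching is a deliberate
non-goal. Scanning is greedy left-to-right longest-match on word
boundaries, producing non-overlapping spans with 0-based half-open
offsets. Lexicon collisions between distinct terms resolve to the
higher-IC term (ties to the smaller id) and are logged, preferring the
clinically more specific reading.

## Network export

A similarity matrix becomes an association network by keeping pairs whose
score is strictly greater than the threshold — ties at the threshold are
excluded, so raising the threshold monotonically shrinks the edge set.
Score histograms use equal-width bins over the off-diagonal values, each
unordered pair counted once. Subnetwork selection induces on a picked
node set, optionally closed under direct neighbors. GraphML and
cytoscape.js-style JSON exports embed node metadata (label, IC, degree)
so a generic viewer can render term information; layout and rendering are
out of scope.

## Synthetic data

The generator emulates the gross shape of an HPO-style resource, not its
statistics. Ontologies grow by attaching each new term to 1..max_parents
earlier terms — acyclic and single-rooted by construction. Entities draw
2–4 direct annotations by default, choosing a leaf with probability 0.7,
mimicking the specificity of curated annotation; noisy patient profiles
take one entity's annotations (8 by default in the denoising experiments,
a realistic deep-phenotyping profile size) plus uniformly drawn noise
terms (2 by default). A master seed fans out through fixed spawn keys so
fixtures are independent and regeneration is byte-identical.

What the generator does not emulate: HPO's depth and branching
distributions, term-frequency skew, annotation biases between disease
databases, or correlated noise in clinical text. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under controlled conditions, not clinical performance on real
HPO data.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale inputs chosen to
exercise every code path while completing in seconds: oracle checks on
100 random DAGs of up to 50 terms, 20 PageRank networks against a dense
solve, 100-seed planted-noise recovery on a 120-term / 30-gene corpus,
and 200 p-value replicates at M = 200. Floating-point comparisons in the
closed-form tests use 1e−12 absolute tolerance (pure arithmetic), the
PageRank oracle 1e−8 (iterative vs direct solve), and TSV writers emit
`repr` of floats so round-trips are exact.

## Known limitations

* Similarity is MICA-based throughout; graph-based measures in the Wang
  family are not implemented.
* The permutation null ignores IC composition and term co-occurrence.
* Text mapping has no negation handling ("no renal cysts" still maps) and
  is monolingual.
* The phenotype network treats `is_a` edges as undirected during the
  walk; direction-aware diffusion is not explored.
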