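# Methods

## Ontology model

The phenotype ontology is a rooted DAG over `is_a` edges only
(`part_of` and cross-ontology edges are out of scope). `A{t}` denotes
the reflexive ancestral closure of a term, `C{t}` the reflexive
descendant closure. `C{t}` is deliberately the *full* closure rather
than direct children: the information-content denominator `‖d{C{t}}‖`
must count every disease annotated anywhere at or below *t*, which is
the standard frequency semantics for annotation-based IC.

Obsolete terms are excluded at load time and rejected in queries with an
explicit message; ids listed as `alt_id` on a live term are silently
remapped to it (logged). An ontology with several parentless terms is
refused unless a synthetic super-root is requested, since a real
phenotype ontology has a single root but toy inputs may not.

## Term weights

Two term-weighting systems coexist:

- **Catalog information content** `ic(t) = −log(‖d{C{t}}‖/N)` (natural
  log, nats), defined only on terms with at least one annotation at or
  below them. `N` counts annotated diseases only. The sign convention
  makes rarer terms *more* informative, and the MICA search maximizes
  IC; this is the standard Resnik reading. Terms with no annotations
  are excluded from catalog-weighted metrics entirely, and query terms
  falling outside the annotated set are dropped with a log entry.
- **Topological information** needs no catalog: `tpc(root) = 1` and
  `tpc(t) = Π over parents p of [tpc(p)/|direct children of p|]`,
  evaluated in topological order; `tic = −log(tpc)`. On wide, deep
  ontologies the product underflows double precision to exactly 0; such
  terms are clamped to `tic = 2.225074e−308` (the minimum normal
  double) so downstream sums stay finite without inventing weight. The
  recursion is isolated in one function so an alternative reachability
  definition can be substituted.

## Similarity metrics

All four metrics operate on term *sets*. For the symmetrized Resnik
score, the printed form "avg[Σ_{t₁∈D} max …]" is evaluated as the
arithmetic mean over the outer terms (best-match average); a literal
average of a single sum would be a no-op and would let scores grow with
annotation count. Scores are symmetric in (Q, D), and their units are
metric-specific (nats for Resnik/IC-weighted, a node count for ATO);
scores are never compared across metrics.

Ranking over the catalog sorts descending by score with competition
ranking ("1224"): tied scores share the smallest rank, and ties are
broken by disease id ascending purely to make output deterministic.

Class signal-to-noise for a disease grouping is the quotient of the mean
within-class pairwise similarity (each unordered pair once, no
self-pairs) and the mean (member, non-member) similarity. A class whose
between-class mean is exactly zero has no defined SNR and raises rather
than reporting infinity.

## Transitive prioritization

`S_T(G,Q) = F(S(D_i,Q))` over the gene's *qualified* diseases, with
`F = max` by default (mean and sum are provided for comparison, along
with the two historical alternatives: scoring a gene by the collapsed
union of its diseases' phenotypes, and by a direct term-to-gene
annotation table). Genes with no qualified supporting disease are
reported separately rather than given a pseudo-score, keeping ranks
meaningful. All variants in one gene share its score; within a gene,
variants are ordered by pathogenicity descending, then MAF ascending
(missing MAF treated as rarest), then position — the within-gene order
is presentational, not part of the model.

The qualification filters are applied in a fixed order (gene-linked,
exome-linked, inheritance model, required phenotypes, curatorial
exclusions); each is a pure subset operation, so relative score order is
invariant and only ranks are recomputed. Required-phenotype matching is
ancestral by default (a disease satisfies a required term if the term
lies in the ancestral closure of its annotations); exact matching is
available via a flag. The inheritance model treats a gene as
recessive-compatible when it carries a homozygous variant or at least
two distinct variants — phase is unknown in single-sample data, so
*possibility* of a compound heterozygote suffices. Diseases whose
declared inheritance mode is unknown are unaffected by model filters
(conservative). Bare gene lists carry no zygosity, so inheritance
constraints are refused for them.

Exonic frameshift variants lacking a pathogenicity score are assigned
1.0 at load time.

## Map and radar layouts

Similarities become dissimilarities by subtracting from the maximum
observed score; the diagonal is then forced to 0 because the Resnik
self-score is not guaranteed to be the global maximum. Classical
(Torgerson) MDS double-centers −D²/2, eigendecomposes, and scales the
top-k eigenvectors by √λ. Axes with non-positive eigenvalues (input not
Euclidean-embeddable in k dimensions) are zeroed with a warning rather
than given imaginary coordinates. Each coordinate column is
sign-canonicalized (first nonzero entry positive) so layouts are
bit-reproducible; MDS output is otherwise unique only up to reflection.

A query is projected as the convex combination of its `m` most similar
diseases (default m = 5), weighted by similarity normalized over those
m; the projection therefore always lies in the neighbors' convex hull,
and an all-zero neighborhood is an error that suggests switching
metrics.

The radar layout places candidates at exact radius
`r_D = (S(Q,Q) − S(Q,D))/S(Q,Q)` and spreads the 1-D MDS range over
`360·(n−1)/n` degrees: scaling across the full 360° would place the two
extreme candidates at the same angle. Point size encodes
`−log10(max(MAF, 1e−6))` of the most pathogenic patient variant in any
linked gene (missing MAF renders at maximum size, i.e. rarest); color
encodes that variant's pathogenicity; diseases with no linked variant
get sentinel (`NA`) encodings.

Computing a full n² similarity matrix on a realistic catalog is
expensive, so the map pipeline also accepts a precomputed square TSV
matrix; the shipped demonstrations are desk-scale synthetic catalogs.

## Discovery

Training genes are the union of gene links over the top-m scored
diseases, where unlinked diseases do not consume slots. Candidates are
patient variant genes outside the training set, scored by the count of
training-gene neighbors and by the fraction of their PPI degree that is
training; the fraction orders results by default (count, then symbol,
break ties). Training genes themselves are never candidates — a known
disease gene is a prioritization hit, not a discovery. The minimum-link
threshold defaults to 1; a stricter neighborhood uses 2.

The premise check compares shortest-path PPI distances between each
gene-linked disease's genes and those of its nearest semantic neighbor
(best-scoring other linked disease) against distances for seeded random
disease pairs, summarized by the two-sample KS statistic. Unreachable
gene pairs receive distance diameter + 1, where the diameter is the
largest eccentricity over connected components; this penalizes
disconnection without an infinite sentinel distorting the KS statistic.

## Synthetic data generator

The generator emulates the shape of the real inputs at desk scale with
every draw fixed by one seed; identical configs yield byte-identical
files.

- **Ontology**: a balanced tree (default depth 4, branching 4, 341
  terms) with probability-0.1 extra within-branch parents, so closures
  are exercised on a true DAG. The root's children partition terms into
  *branches*.
- **Diseases** (default 24 in 3 classes): each class draws from its own
  branch and classmates share `class_coherence` fixed terms (default
  3); every non-planted disease also draws one incidental term from
  anywhere (`cross_branch_noise = 1`), mirroring the minor-feature
  overlap of real disease classes — without it, between-class Resnik
  similarity is exactly zero and the SNR undefined. At coherence 0,
  terms are drawn uniformly from the whole ontology, erasing class
  structure by construction. Consecutive classmates share a gene, so
  aggregation choice matters; each disease gets a dominant or recessive
  inheritance mode.
- **Case**: the planted disease (branch-pure by construction) donates
  its term set to the query, optionally plus noise terms from a branch
  no class uses, so truth recovery is unambiguous. Its gene receives a
  homozygous (or compound-heterozygous) variant; decoy genes from other
  classes receive single het variants. MAFs are log-uniform in
  [1e−6, 1e−2] — everything passes the conventional >1 % pre-filter —
  and pathogenicities uniform in [0.5, 1].
- **PPI**: class genes form cliques joined through a two-hop hub
  scaffold, so within-class gene distances are 1 and cross-class
  distances ≥ 4. The planted discovery candidate (a non-catalog variant
  gene) is wired only to planted-class genes; decoy candidates get
  exactly one catalog link plus two non-catalog pads, capping their
  training fraction at 1/3.

What the generator does **not** emulate: realistic term-frequency
distributions, annotation depth imbalance between diseases, genes
linked to many unrelated diseases, scale (thousands of diseases,
hundreds of variant genes), or PPI degree distributions. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under clean planted signal, not clinical performance on real cohorts.

## Problem sizes and numeric choices

The verification suite and the acceptance script use: 200 random
fixtures (≤ 30 terms, ≤ 10 diseases) for exact-agreement oracle checks
(ATO exact integers, weighted metrics at 1e−10 relative); 100 seeded
cases with 20 decoy genes (60 diseases) for rank recovery; 100 seeded
cases for curation monotonicity and discovery recovery; 10 random
planar point sets (n ≤ 10) for MDS reconstruction at 1e−6 relative
distance error; 200 background pairs for the KS comparison. These sizes
make the full suite run in seconds while leaving the planted effects
far from the decision thresholds.

Determinism: all simulation randomness flows from `random.Random(seed)`
or `numpy.random.default_rng(seed)`; TSV floats are written at fixed
precision; session JSON is key-sorted. Natural logarithms throughout
(the log base only rescales scores and never changes a rank, but fixing
it keeps numbers reproducible).

## Known limitations

- Single-sample analysis only: no trio/de-novo logic and no
  MAF-based pre-filtering (inputs are expected pre-filtered).
- Free-text phenotype extraction is out of scope; queries are term-id
  sets.
- Gene alias handling is table-driven (user-supplied two-column TSV),
  not a live nomenclature service.
- The global map is a lossy projection; radial positions on the radar
  layout are exact, but its angles are a 1-D approximation of
  inter-candidate structure.
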