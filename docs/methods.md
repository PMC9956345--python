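# Methods

## Model and assumptions

`variclust` stratifies a cohort from a variant-event catalogue under three
assumptions: (i) the biological signal of interest is *which genes* are hit
in an individual, not the molecular detail of each variant — events are
reduced to per-individual gene sets; (ii) a pretrained gene co-expression
embedding places functionally related genes near each other, so a vector
built on its column space inherits functional structure; (iii) phenotype →
gene annotation lists carry genotype–phenotype information that is worth
baking into the coordinate system before measuring individual similarity.

### Vectorisation: the max-of-components rule

Each gene g with embedding vector v_g ∈ R^D contributes the scalar
s_g = max_d v_{g,d}.  A phenotype annotated with gene set A becomes the
G-vector with s_g at columns g ∈ A (in-vocabulary) and 0 elsewhere; an
individual with variated-gene set S is vectorised identically.  The same
rule is deliberately used for both: the encoder is trained on phenotype rows
and applied to individual vectors, which is only coherent if both live in
the same column space with the same per-gene scalars.  The true maximum is
taken even when every component is negative, and matrix entries are *stored*
by annotation membership rather than by non-zero value, so a coincidental
0.0 maximum remains a stored entry.  "Sequence of genes" is treated as an
unordered set — the encoder input is a fixed-width vector, so order cannot
matter and duplicates collapse.  Out-of-vocabulary genes are dropped and
counted, never imputed.  Phenotype rows left with no in-vocabulary gene are
flagged and excluded from autoencoder training (but kept in the matrix);
individuals whose sets empty out are retained and flagged.

### Deduplication

The duplicate key is (individual, chrom, pos, ref, alt) when the genomic
descriptor is complete, else (individual, gene, category); the first
occurrence in input order is kept.  Coordinates are pass-through text — the
method performs no coordinate arithmetic, so no 0/1-based interpretation or
variant normalisation (left-alignment, allele re-representation) is
attempted, and no deleteriousness or frequency classification is made.

### Autoencoder

Symmetric dense autoencoder: six encoding layers whose widths follow a
geometric ramp from G down to the 64-component latent code, mirrored by six
decoding layers.  Hidden units are rectified linear; the latent and output
layers are linear (a linear latent keeps latent distances comparable for the
downstream metric step).  Training is mean-squared-error reconstruction with
the Adam optimiser (learning rate 10⁻³, batch 32, 200 epochs by default),
implemented directly in numpy with He initialisation; all randomness
(initialisation, shuffling) flows from a mandatory seed and training is
bit-reproducible on one thread.  No input normalisation is applied by
default — embedding components already share a scale — with optional min–max
scaling by flag.  The encoder is frozen before any individual is encoded;
individual vectors never influence training.

### Clustering and validation

UMAP (15 neighbours, 5 components, cosine metric, fixed `random_state`,
hence single-threaded and reproducible) reduces the latent matrix before
density clustering; a separate 2-component projection is exported for
plotting only.  HDBSCAN (scikit-learn implementation) is evaluated over an
exhaustive grid of min_cluster_size × min_samples × {euclidean, manhattan} ×
{eom, leaf}.  "Grid search cross validation" here means exhaustive
enumeration scored on the full data — clustering has no held-out labels and
DBCV is the only selection metric.  DBCV is implemented from its published
definition: all-points core distances (inverse generalized mean of inverse
distances, exponent = space dimensionality), mutual-reachability distances,
per-cluster MSTs, density sparseness = largest internal MST edge (edges
between nodes of MST degree > 1; maximum MST edge for clusters too small to
have any), density separation = minimum mutual reachability between internal
nodes, validity per cluster (sep − spr)/max(sep, spr), summed with weights
|C_i|/N where N counts noise points too.  Two numerical conventions matter:

* **MST tie-break.**  Mutual-reachability graphs contain many exactly tied
  edges (any pair dominated by the same core distance), and the DBCV value
  depends on which MST is realised.  Prim's algorithm is therefore run with
  a canonical rule — minimum weight, then lexicographically smallest
  (min node, max node) pair — and the test-suite oracle implements the same
  rule independently; agreement is checked to 10⁻⁹.
* **Undefined scores.**  With fewer than two clusters of size ≥ 2 the index
  is undefined; grid search ranks such cells below every defined score, and
  a grid whose every cell is undefined is a fatal error with the full table
  attached.

DBCV is always computed with Euclidean distances in the reduced space,
regardless of the HDBSCAN metric under evaluation, so scores are comparable
across grid cells.  Grid ties are broken by higher coverage, then larger
min_cluster_size, then grid order.  Coverage is the fraction of individuals
assigned to any cluster.

### Enrichment

For cluster gene set with n in-background genes, term with K background
genes, overlap k, background N: FE = k/(n·K/N); significance is the
two-tailed Fisher exact p on [[k, n−k], [K−k, N−n−K+k]] (two-sided in the
standard sense: summing hypergeometric outcomes no more probable than the
observed table); BH adjustment forms **one family per cluster across all
namespaces jointly**, because reports mix namespaces under a single FDR
column.  Reporting rules: primary = {FDR < 0.005 and FE ≥ 1.5} ranked by FE
descending; if empty but significant terms exist, fallback = top 20 by FDR;
empty reports are legitimate.  The default background universe is the genes
present in both the embedding vocabulary and the annotation database (kept
identical between the term and phenotype analyses so FEs are comparable);
"all annotated genes" is available by flag.  Annotation sets are used
exactly as listed — no ontology-graph propagation by default, no minimum
term size by default; both are configurable and recorded.  Phenotype FE
reuses the same formula with the phenotype's in-background gene set as the
term and carries no p-value; the report shows FE > 1.0 ranked by FE.

## Synthetic data: what it emulates and what it does not

The generator plants structure in *embedding space* — the only space the
pipeline actually consumes: M unit-norm module centroids (rejection-sampled
until pairwise |cosine| < 0.5), gene vectors = centroid + N(0, σ²) per
component.  Phenotypes and ontology terms draw a fraction ρ of their genes
from a home module; individuals of subtype s draw a fraction f from module
m(s).  Duplicate rows (re-reports by a second source paper) and
out-of-vocabulary symbols are injected at configurable rates to exercise
ingestion edge paths.  Every generator is a pure function of the config;
per-product random streams are derived from the seed with fixed offsets, so
regeneration is byte-identical.

Default study conditions: G = 300 genes, D = 50 dimensions, M = 6 modules,
σ = 0.05, P = 120 phenotypes (12 genes each, ρ = 0.8), T = 42 terms
(14 genes each), S = 3 subtypes × 60 individuals, 40 genes per individual,
f = 0.9, duplicate rate 0.05, OOV rate 0.02.  The 40 genes/individual figure
mirrors real whole-genome catalogues, which average roughly forty
deduplicated events per individual; it also sets the detectability regime —
with draws much sparser than ~half the module size, within-subtype gene-set
overlap shrinks and recovery degrades.  The property suite sweeps the
planted-signal dials end to end: ARI rises monotonically with the
subtype-module fraction f (from chance at f = 0.3 to ≈ 1 at f = 0.9), while
growing the module spread σ leaves recovery intact within sampling noise —
subtype recovery is driven by which genes an individual's set *supports*,
not by how tightly the embedding modules cluster, so σ chiefly affects the
phenotype-matrix geometry rather than cohort separability.  What the
generator does **not** emulate:
the heavy-tailed per-gene variant frequency spectrum of real catalogues, the
ontology's graph topology (annotations are flat lists), linkage between
phenotype lists and term lists beyond shared modules, and any notion of
variant pathogenicity.  Passing the planted-recovery tests therefore shows
the pipeline recovers modular gene-set structure under realistic sparsity —
not that real cohorts contain such structure.

## Numerical choices and degenerate inputs

* Autoencoder training aborts on a non-finite loss (with the epoch index)
  and on fewer than two usable rows; geometric widths are forced strictly
  decreasing after rounding.
* The model archive is a fixed-date zip of the weight arrays plus a JSON
  config echo, so identical models are byte-identical on disk.
* Coincident points (individuals with identical gene sets) give zero
  pairwise distance; their all-points core distance is 0 and the MST shift
  used internally handles zero-weight edges exactly.
* `min_cluster_size` larger than the sample count yields an all-noise
  labelling with a warning rather than an error, so grids can safely bracket
  small cohorts.
* Fisher tables are validated cell-by-cell; FE with an empty term or empty
  cluster raises a distinct "undefined term" error and the term is skipped.
* Per-stage seeds derive from the global seed via `numpy.random.SeedSequence`
  spawn state (reduced mod 2³¹), recorded in the run report, so stages can be
  rerun in isolation.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at the
default synthetic conditions (180 individuals, G = 300, 120 autoencoder
epochs, an 8-cell clustering grid); oracle-equivalence suites use instances
of n ≤ 60 points for DBCV and N ≤ 200 for exact Fisher enumeration, where
brute force is exact and fast.  These sizes were chosen as the smallest at
which every contract of interest is exercised with comfortable margins.

## Known limitations

* No HGNC alias resolution: gene symbols are matched after uppercasing and
  trimming only; catalogues and annotation files using divergent symbol
  vintages will silently shrink the background.
* The latent geometry of any particular trained autoencoder is not
  identifiable — different seeds give different (equally valid) encoders;
  contracts are therefore stated as properties (distance rank-correlation,
  reconstruction error, determinism) rather than coordinates.
* DBCV is O(n²) per cluster in memory and time; cohorts beyond a few tens of
  thousands of individuals would need a subsampled score.
* The enrichment stage inherits whatever biases the annotation database
  carries; no attempt is made to correct for gene length, study bias or
  annotation depth.
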