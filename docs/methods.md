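# Methods

`ldalink` implements a de-noising and link-prediction strategy for paired
host-gene and microbe abundance tables from heterogeneous samples (the
motivating setting is induced-sputum RNA-seq from an asthma cohort, where
one library yields both human gene expression and exogenous microbial
reads).  This note records the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Data model

All stages consume patients x entities matrices (`AbundanceTable`): a gene
table **G** (N_p x N_g, non-negative FPKM/TPM/RPM-like values), a microbe
table **M** (N_p x N_m relative abundances), an optional clinical table
**C** (mixed numeric, missing values allowed), and cell-fraction tables
**F** produced by deconvolution.  Units are treated as opaque non-negative
abundances; the declared unit is carried as metadata only.  Gene and
microbe tables must be dense; clinical tables are handled downstream with
pairwise-complete deletion, since clinical registries are sparse while
count tables are not.

Taxonomic rollup (`rollup_taxa`) sums microbe columns to a requested rank;
leaves without a mapping are pooled into an `unclassified` column rather
than dropped, so per-patient totals are conserved exactly.  Patient
clustering on rolled-up profiles uses Ward linkage on Euclidean distance
of row-renormalized (compositional) profiles — the common default for
heatmap-style clustering; rows are renormalized so grouping reflects
composition rather than depth.

## Topic models

Both tables are de-noised with latent Dirichlet allocation: a patient is
a document, genes or microbes are words, and the scaled integer abundance
is the word count.  Abundances are converted to tokens by rounding to the
nearest integer (round-half-to-even — the convention is configurable since
several are defensible), dividing by 10, flooring, and capping at 1000;
the cap bounds the token count so exact token expansion stays tractable.

Inference is collapsed Gibbs sampling.  With symmetric priors alpha (topics
in documents) and beta (words in topics), each token's topic is resampled
from

    P(z = k | Z_-, W) ∝ (n_{k,v}^- + beta) / (n_k^- + N_v beta) * (n_{p,k}^- + alpha)

with the token's own counts removed.  The sweep kernel is compiled with
numba; every random draw is taken from a single numpy Generator outside
the kernel, so a fit is bit-reproducible under its seed.  Correctness of
the conditional is tested against a brute-force oracle that evaluates the
collapsed joint (a product of multivariate-beta ratios) from scratch for
every topic choice of every token on tiny corpora.

Point estimates are read off the smoothed counts:

    theta_{p,k} = (n_{p,k} + alpha) / (n_p + N_k alpha)
    phi_{k,v}   = (n_{k,v} + beta)  / (n_k + N_v beta)

Defaults: `n_topics = 10`, `alpha = 0.5`, `beta = 0.1`, 1000 sweeps with
500 burn-in, estimating from the final state (the estimators are defined
per state; averaging the estimator over post-burn-in sweeps is available
via `estimate_mode="average"` but is not the default, because averaging
mixes states across possible label switches).  Topics are reported in
descending order of total mass; label switching across seeds is expected
and all evaluations match topics by best permutation.  Documents with zero
tokens after scaling are dropped with a warning, not imputed.  The
training-corpus collapsed log joint is tracked per sweep as a convergence
trace.

## Correlation engine

Cross-table screens compute the product-moment correlation of every
column pair over shared patients, with two-sided p-values from the
t-transform with n-2 degrees of freedom (an exact permutation p-value is
available for small n).  Spearman (rank) correlation is selectable.
Constant or too-sparse columns yield flagged missing values, never zero.
All pairs tested in one call form a single Benjamini-Hochberg family
(flattened row-major); families from different screens are never pooled
silently.  Missing clinical entries are handled pairwise-complete with
the per-pair n recorded.

## Self-supervised link prediction

No gold standard exists for gene-microbe links, so one is manufactured
from the data: pairs with |r| > 0.4 and p < 1e-5 become positive labels
(absolute correlation, so strong negative couplings count), and an
equal-sized seeded uniform sample of pairs with |r| < 0.05 becomes the
negatives.  Negative sampling happens once per run, not per CV repeat.

Each pair is featurized in topic space: the gene's column of phi^G
concatenated with the microbe's column of phi^M (length 2 N_k = 20 at the
default ten topics).  Each entity's column is L1-normalized before use so
rare and abundant entities are comparable; raw columns are available via
`normalize=False`.  A random forest (500 trees, sqrt feature sampling, no
depth cap, probability = fraction of trees voting positive) is trained on
these features; per-feature Gini importances are reported as
"gene topic k" / "microbe topic k".

Validation uses a strict left-out protocol: 10% of labeled pairs are held
out, and every remaining pair sharing a gene OR a microbe with the
held-out set is removed from training, leaving slightly less than 90%.
Entity disjointness between train and test is asserted, not assumed.  Ten
repeats give per-repeat AUCs and a pooled ROC.  A repeat whose entity
removal empties a class is resampled with bounded retries.

Prediction scores every non-training pair (exact-pair exclusion by
default; entity-level exclusion is an option) and flags probability >
0.95 (strict inequality) as high confidence.  Output is sorted by
descending probability with lexicographic tie-breaks so files are
deterministic.

## Supervised deconvolution

Cell fractions solve G = F S' per patient: the signature-gene profile is
regressed on the reference cell-type signatures with linear nu-SVR over
the grid nu in {0.25, 0.5, 0.75}, keeping the lowest-RMSE fit.  The
support-vector machinery performs gene selection, which curbs
overfitting.  The signature matrix is standardized globally (one mean and
sd for the whole matrix) and each patient profile per sample — both
transforms are affine, so after clipping negative coefficients and
renormalizing to the simplex the fraction estimates are unchanged by the
scaling.  Goodness of fit is the correlation between reconstructed and
observed profile; its permutation p-value shuffles the profile's gene
labels and refits with the winning nu (100 permutations by default).
Signature expansion to all genes solves the same equation for S via the
pseudoinverse of F, requiring full column rank (collinear cell types are
named in the error) and clipping negative inferred expression with a
logged count.  `aggregate_cell_types` sums fraction columns into named
groups (e.g. M0+M1+M2 -> macrophages) for comparison with lower-resolution
counts.

## Co-abundance networks

Microbe profiles — raw abundance columns or phi^M topic columns — are
thresholded on Pearson correlation: an edge requires r >= cutoff, with
defaults 0.3 for raw profiles and 0.8 for topic profiles (short,
de-noised vectors correlate more tightly).  Positive correlation only, as
befits co-abundance; |r| mode is available.  Modules are detected by
edge-betweenness division (dendrogram cut at maximum modularity — the cut
rule had to be fixed here), seeded asynchronous label propagation, or
fast-greedy modularity.  A microbe is labeled with topic k when it ranks
in the top 10 contributors to topic k; ties at the boundary are all
included, and multiple labels per microbe are expected.

## Synthetic cohorts and what they show

The generators emulate the statistical structure the method assumes, at
sizes that keep a full run in minutes:

* `gen_lda_corpus` draws documents exactly from the LDA generative model
  with near-disjoint planted topics, so topic recovery is measurable by
  best-permutation cosine similarity.
* `gen_linked_tables` (defaults: 115 patients, 2000 genes, 200 microbes,
  10 latent factors) gives each patient Dirichlet(0.3) factor weights.
  Six factors drive microbes (log-normal noise sd 1.0, so same-factor
  microbes co-vary moderately), four drive gene-only expression programs
  (noise sd 0.5), and half of each table is factor-free noise.  Planted
  linear links set gene = a*microbe + noise with noise sd = 0.75 of the
  signal sd, i.e. r = 1/sqrt(1+0.75^2) ≈ 0.8 — strong enough that at
  n = 115 every such pair passes the |r| > 0.4, p < 1e-5 gate with large
  margin.  Planted threshold links switch a gene on above the microbe's
  70th-percentile abundance with noise calibrated to keep the
  point-biserial correlation near 0.3, below the gate, while the gene
  still inherits the microbe's factor pattern — the mechanism the topic
  features are supposed to catch and the linear screen misses.
* `gen_mixtures` builds a well-conditioned block-marker signature matrix,
  Dirichlet(0.8) fractions, and additive Gaussian noise scaled to the
  mean signal.

Deliberately not emulated: per-patient compositional closure of the
microbe table (closure couples unrelated columns and would contaminate
the negative labels), sequencing-depth variation, batch effects, zero
inflation, and taxonomic realism.  Passing benchmarks on these cohorts
therefore demonstrates correctness and power of the machinery under the
model's own assumptions, not performance on real sputum data, where
compositional and batch artifacts add failure modes the generator does
not produce.

## Problem sizes and runtime

Benchmarks and the acceptance script run scaled-down cohorts chosen once:
115 patients x 900 genes x 200 microbes with 80 linear and 40 threshold
links for the link-prediction checks (400 Gibbs sweeps per table) — the
planted-link density is set so each microbe factor carries enough linked
genes (~13) for the gene topic model to allocate them a topic, which the
classifier's features depend on; a separate 115 x 100 x 50 cohort with 30
planted strong pairs among 5000 measures pseudo-gold recall;
100 x 50 corpora with 1000 sweeps for topic recovery; 60 patients x 8 cell
types x 400 signature genes with 10% noise and 100 permutations for
deconvolution; 30-node planted three-block graphs for module detection.
Full-scale tables (20,000 genes, 1000 microbes) are supported — token
expansion at the default count scaling stays bounded by the 1000-count
cap — just slower.

## Known limitations

* Single-chain, single-sample estimation; no convergence diagnostics
  beyond the log-joint trace.
* The t-approximation for correlation p-values is anti-conservative for
  heavy-tailed abundances at small n; the permutation option exists but
  is not the default.
* The pseudo-gold standard inherits any confounding that produces strong
  linear correlations; labels are self-supervised, not curated truth.
* nu-SVR deconvolution assumes the reference signatures span the mixture;
  missing cell types bias fractions toward the nearest available ones.
* Edge-betweenness module detection is O(E^2 V)-ish and becomes slow
  beyond a few thousand edges; label propagation or fast-greedy are the
  practical choices there.
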