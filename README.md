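# ldalink

Topic-model de-noising and self-supervised link prediction for paired
host-gene and microbe abundance tables.

## The problem

Bulk RNA-seq of heterogeneous samples such as induced sputum captures two
things at once: human gene expression (a patients x genes table **G**) and
exogenous microbial reads (a patients x microbes table **M**).  Direct
correlation screens between the two tables find only the strongest linear
couplings — the data are noisy, heterogeneous mixtures of cell types, and
biologically interesting responses (e.g. a gene switched on only when a
microbe passes an abundance threshold) are invisible to a linear gate.

`ldalink` addresses this with a three-step strategy:

1. **De-noise both tables with latent Dirichlet allocation.**  Patients
   are documents, genes/microbes are words, scaled abundances are word
   counts.  A collapsed Gibbs sampler yields the patient-topic tables
   theta (N_p x N_k) and topic-word tables phi (N_k x N_g / N_k x N_m),
   with posterior-mean estimates
   theta_{p,k} = (n_{p,k}+alpha)/(n_p+N_k alpha) and
   phi_{k,v} = (n_{k,v}+beta)/(n_k+N_v beta).
2. **Manufacture a pseudo-gold standard.**  Pairs with |r| > 0.4 at
   p < 1e-5 (BH-corrected family reported alongside) are positive labels;
   an equal number of |r| < 0.05 pairs are sampled as negatives.
3. **Train a random-forest link classifier on topic features.**  Each
   gene-microbe pair is the concatenation of its two phi columns (length
   2 N_k = 20); the model is validated by strict left-out cross-validation
   (held-out pairs share no gene and no microbe with training) and then
   scores every remaining pair, flagging probability > 0.95 links as high
   confidence.

Companion modules provide supervised cell-type deconvolution by nu-SVR
(G = F S', with permutation fit p-values and expansion of signatures to
all genes), microbe co-abundance networks with module detection and topic
labeling, taxonomy rollup with hierarchical patient clustering, and
synthetic data generators with retained ground truth.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

Run the whole pipeline on a synthetic cohort (115 patients, planted
topics and planted gene-microbe couplings, ground truth retained):

```bash
ldalink run-all --seed 42 --out runs/demo
```

or, from Python, with the scaled-down cohort used in the benchmarks:

```python
from ldalink.cli import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=42, n_genes=900, n_microbes=200,
                     n_linear_links=80, n_threshold_links=40,
                     n_sweeps=400, burn_in=200)
manifest = run_pipeline(cfg, "runs/demo")
```

The run directory contains, per stage: the simulated tables and truth
(`simulate_*`), theta/phi TSVs and a log-likelihood trace for both topic
models (`lda_genes_*`, `lda_microbes_*`), the long-format correlation
screen with r/p/q per pair, the labeled pseudo-gold standard, per-repeat
CV AUCs and the pooled ROC, the ranked link table, Gini importances,
co-abundance edge lists and module tables for both raw-abundance and
topic-based networks, deconvolution fractions with fit statistics, and a
`manifest.json` recording seeds, config hash and per-stage row counts.

This configuration finishes in about 3.5 minutes on one CPU and its
manifest reports:

```
pseudo_gold:   537 positives, 537 negatives
link_cv:       mean AUC over 10 repeats = 0.830
link_predict:  178926 pairs scored, 542 high-confidence (probability > 0.95)
network:       1286 raw-abundance edges, 1944 topic-based edges
```

All 80 planted strong linear couplings (calibrated to r ~ 0.8) land among
the positives.  Of the planted threshold-mechanism couplings — whose
linear correlation sits near 0.3, below the gate — 13 of the 37 scored
rank in the top decile of predicted probabilities (3.5x over chance,
versus essentially zero recovered by the linear gate): non-linear
relationships the correlation screen cannot see.

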