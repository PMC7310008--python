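"""Synthetic fixture generators with retained ground truth.

Every input the pipeline consumes can be generated here: a token corpus
with planted topics for the Gibbs sampler, paired gene/microbe abundance
tables with planted linear and threshold-mechanism couplings riding on a
shared latent topic structure, and cell-type mixtures for deconvolution.
All generators are deterministic under their seed and return the ground
truth alongside the data so recovery can be measured.

The default cohort emulates the shape of an induced-sputum study:
115 patients, ~2,000 genes (RPM-like expression) and ~200 microbes
(relative abundance reported as reads per 10,000 exogenous reads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, ScaledCounts

__all__ = [
    "SyntheticTruth",
    "gen_lda_corpus",
    "gen_linked_tables",
    "gen_mixtures",
]


@dataclass
class SyntheticTruth:
    """Ground truth retained by a generator; JSON-serializable."""

    theta_true: pd.DataFrame | None = None
    phi_true: pd.DataFrame | None = None
    planted_links: list[tuple[str, str, str]] = field(default_factory=list)
    F_true: pd.DataFrame | None = None
    S_true: pd.DataFrame | None = None
    entity_topics: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path) -> None:
        payload: dict = {"seed": self.seed, "planted_links": self.planted_links,
                         "entity_topics": self.entity_topics}
        for name in ("theta_true", "phi_true", "F_true", "S_true"):
            frame = getattr(self, name)
            if frame is not None:
                payload[name] = {
                    "index": list(frame.index),
                    "columns": list(frame.columns),
                    "values": frame.to_numpy().tolist(),
                }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def gen_lda_corpus(
    n_docs: int = 100,
    n_vocab: int = 50,
    n_topics: int = 3,
    alpha_doc: float = 0.1,
    topic_sparsity: float = 0.95,
    tokens_per_doc: int = 200,
    seed: int = 0,
) -> tuple[ScaledCounts, SyntheticTruth]:
    """Corpus drawn from the LDA generative model with planted topics.

    Topic-word rows are near-disjoint: each topic concentrates a
    ``topic_sparsity`` fraction of its mass on its own vocabulary block,
    the remainder spread over the whole dictionary, so recovered and true
    topics can be matched by cosine similarity.  Documents' topic weights
    are Dirichlet(``alpha_doc``) and token counts multinomial.
    """
    if n_topics > n_vocab:
        raise ValueError("need at least one word per topic (n_topics <= n_vocab)")
    if not 0 < topic_sparsity <= 1:
        raise ValueError("topic_sparsity must be in (0, 1]")
    rng = np.random.default_rng(seed)

    blocks = np.array_split(np.arange(n_vocab), n_topics)
    phi = np.full((n_topics, n_vocab), (1 - topic_sparsity) / n_vocab)
    for k, block in enumerate(blocks):
        within = rng.dirichlet(np.ones(len(block)) * 5.0)
        phi[k, block] += topic_sparsity * within
    phi /= phi.sum(axis=1, keepdims=True)

    theta = rng.dirichlet(np.ones(n_topics) * alpha_doc, size=n_docs)
    counts = np.stack([rng.multinomial(tokens_per_doc, theta[d] @ phi)
                       for d in range(n_docs)])
    doc_ids = [f"P{d:03d}" for d in range(n_docs)]
    vocab = [f"w{v:03d}" for v in range(n_vocab)]
    cap = max(1000, int(counts.max()))
    sc = ScaledCounts(pd.DataFrame(counts.astype(np.int64), index=doc_ids, columns=vocab), cap=cap)
    truth = SyntheticTruth(
        theta_true=pd.DataFrame(theta, index=doc_ids,
                                columns=[f"topic_{k}" for k in range(n_topics)]),
        phi_true=pd.DataFrame(phi, index=[f"topic_{k}" for k in range(n_topics)],
                              columns=vocab),
        seed=seed,
    )
    return sc, truth


def gen_linked_tables(
    n_patients: int = 115,
    n_genes: int = 2000,
    n_microbes: int = 200,
    n_linear_links: int = 30,
    n_threshold_links: int = 30,
    n_topics: int = 10,
    noise_sd: float = 0.75,
    microbe_noise_sd: float = 1.0,
    threshold_quantile: float = 0.70,
    topic_gene_frac: float = 0.5,
    topic_microbe_frac: float = 0.8,
    seed: int = 0,
) -> tuple[AbundanceTable, AbundanceTable, SyntheticTruth]:
    """Paired gene and microbe tables with planted couplings.

    Each patient carries ``n_topics`` latent factor weights
    (Dirichlet(0.3)).  The first 60% of factors are microbe factors: a
    ``topic_microbe_frac`` fraction of microbes tracks one each, with
    log-normal noise (``microbe_noise_sd``) strong enough that two
    microbes of the same factor co-vary moderately rather than tightly.
    The remaining factors are gene-only expression programs followed by
    a ``topic_gene_frac`` fraction of genes; the rest of both tables is
    factor-free noise, emulating the bulk of genes and microbes with no
    cross-table relationship.  Planted couplings then overwrite genes:

    * linear links — gene = a * microbe + Gaussian noise, the noise scaled
      to ``noise_sd`` times the signal sd, giving a pairwise correlation
      of 1/sqrt(1 + noise_sd**2) (~0.8 at the default 0.75);
    * threshold links — the gene switches on only when the microbe exceeds
      its ``threshold_quantile`` abundance quantile, with noise calibrated
      so the linear correlation stays well below the pseudo-gold gate
      while the gene still inherits the microbe's factor pattern.

    Because linked genes ride on microbe factors while background genes
    ride on gene-only programs, the strong linear correlations are
    (almost) exactly the planted linear links plus a penumbra of
    same-factor pairs, as in a sparse real screen.  Both tables carry
    RPM-like magnitudes; per-patient compositional closure of the
    microbe table is not emulated.
    """
    if n_linear_links + n_threshold_links > n_genes * n_microbes:
        raise ValueError("more planted links than gene-microbe pairs")
    if n_topics < 2:
        raise ValueError("need at least two latent factors")
    n_free = n_genes - int(round(topic_gene_frac * n_genes))
    if n_linear_links + n_threshold_links > n_free:
        raise ValueError(
            f"{n_linear_links + n_threshold_links} planted links need as many "
            f"program-free genes but only {n_free} are available; increase "
            "n_genes or lower the link counts"
        )
    rng = np.random.default_rng(seed)
    patients = [f"P{p:03d}" for p in range(n_patients)]
    genes = [f"G{g:04d}" for g in range(n_genes)]
    microbes = [f"m{m:03d}" for m in range(n_microbes)]

    n_microbe_factors = max(1, int(round(0.6 * n_topics)))
    theta = rng.dirichlet(np.ones(n_topics) * 0.3, size=n_patients)

    # --- microbe table -------------------------------------------------
    n_topic_m = int(round(topic_microbe_frac * n_microbes))
    microbe_topic = {microbes[j]: j % n_microbe_factors for j in range(n_topic_m)}
    M = np.empty((n_patients, n_microbes))
    for j in range(n_microbes):
        scale = rng.lognormal(0.0, 0.5)
        lognoise = np.exp(rng.normal(0.0, microbe_noise_sd, size=n_patients))
        if j < n_topic_m:
            M[:, j] = (theta[:, j % n_microbe_factors] + 0.02) * scale * lognoise
        else:
            M[:, j] = 0.1 * scale * lognoise
    # global scale to RPM-like magnitudes (per-patient compositional closure
    # is deliberately not emulated; it would couple unrelated columns)
    M *= 250.0

    # --- gene table ----------------------------------------------------
    n_gene_programs = n_topics - n_microbe_factors
    n_topic_g = int(round(topic_gene_frac * n_genes))
    gene_topic = {
        genes[i]: n_microbe_factors + i % n_gene_programs for i in range(n_topic_g)
    }
    G = np.empty((n_patients, n_genes))
    gene_scale = 20.0  # RPM-like magnitude; ~2 tokens/gene after count scaling
    for i in range(n_genes):
        scale = gene_scale * rng.lognormal(0.0, 0.4)
        lognoise = np.exp(rng.normal(0.0, 0.5, size=n_patients))
        if i < n_topic_g:
            program = n_microbe_factors + i % n_gene_programs
            G[:, i] = (theta[:, program] + 0.02) * scale * lognoise * n_topics
        else:
            G[:, i] = scale * lognoise

    # --- planted links -------------------------------------------------
    # linked genes are taken from the program-free tail so a link's only
    # structure is the planted mechanism; target microbes are factor-driven.
    planted: list[tuple[str, str, str]] = []
    link_gene_idx = rng.choice(
        np.arange(n_topic_g, n_genes), size=n_linear_links + n_threshold_links,
        replace=False,
    )
    link_microbe_idx = rng.choice(np.arange(n_topic_m),
                                  size=n_linear_links + n_threshold_links, replace=True)
    for li in range(n_linear_links):
        gi, mj = int(link_gene_idx[li]), int(link_microbe_idx[li])
        mcol = M[:, mj]
        a = gene_scale / mcol.mean()
        sigma = noise_sd * np.std(a * mcol)
        G[:, gi] = np.maximum(
            2 * sigma + a * mcol + rng.normal(0.0, sigma, size=n_patients), 0.0
        )
        planted.append((genes[gi], microbes[mj], "linear"))
        gene_topic[genes[gi]] = int(microbe_topic[microbes[mj]])
    for li in range(n_linear_links, n_linear_links + n_threshold_links):
        gi, mj = int(link_gene_idx[li]), int(link_microbe_idx[li])
        mcol = M[:, mj]
        cut = np.quantile(mcol, threshold_quantile)
        ind = (mcol > cut).astype(float)
        h = 3 * gene_scale
        pq = threshold_quantile * (1 - threshold_quantile)
        sigma = 2.5 * h * np.sqrt(pq)  # keeps point-biserial |r| ~ 0.3
        G[:, gi] = np.maximum(
            0.5 * gene_scale + h * ind + rng.normal(0.0, sigma, size=n_patients), 0.0
        )
        planted.append((genes[gi], microbes[mj], "threshold"))
        gene_topic[genes[gi]] = int(microbe_topic[microbes[mj]])

    gtab = AbundanceTable(pd.DataFrame(G, index=patients, columns=genes),
                          kind="gene", unit="RPM")
    mtab = AbundanceTable(pd.DataFrame(M, index=patients, columns=microbes),
                          kind="microbe", unit="reads per 10k")
    truth = SyntheticTruth(
        theta_true=pd.DataFrame(theta, index=patients,
                                columns=[f"topic_{k}" for k in range(n_topics)]),
        planted_links=planted,
        entity_topics={"gene": gene_topic, "microbe": microbe_topic},
        seed=seed,
    )
    return gtab, mtab, truth


def gen_mixtures(
    n_patients: int = 60,
    n_cell_types: int = 8,
    n_signature_genes: int = 400,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[AbundanceTable, "pd.DataFrame", pd.DataFrame]:
    """Cell-type mixtures G = F S' + noise for deconvolution tests.

    The signature matrix S' gives each cell type a block of exclusive
    high-expression marker genes over a low common background, so it is
    well conditioned.  Mixing fractions F are Dirichlet(0.8) rows; the
    additive Gaussian noise sd is ``noise_sd`` times the mean signal.

    Returns the mixed signature-gene expression table, the signature
    matrix (cell types x genes DataFrame), and the true fractions.
    """
    if n_signature_genes < 5 * n_cell_types:
        raise ValueError("need n_signature_genes >= 5 * n_cell_types for conditioning")
    rng = np.random.default_rng(seed)
    patients = [f"P{p:03d}" for p in range(n_patients)]
    cells = [f"cell_{f}" for f in range(n_cell_types)]
    sgenes = [f"SG{s:04d}" for s in range(n_signature_genes)]

    S = rng.uniform(0.0, 1.0, size=(n_cell_types, n_signature_genes))
    blocks = np.array_split(np.arange(n_signature_genes), n_cell_types)
    for f, block in enumerate(blocks):
        S[f, block] += rng.uniform(8.0, 12.0, size=len(block))
    F = rng.dirichlet(np.ones(n_cell_types) * 0.8, size=n_patients)
    signal = F @ S
    G = signal + rng.normal(0.0, noise_sd * signal.mean(), size=signal.shape)
    G = np.maximum(G, 0.0)

    gtab = AbundanceTable(pd.DataFrame(G, index=patients, columns=sgenes),
                          kind="gene", unit="TPM")
    sig = pd.DataFrame(S, index=cells, columns=sgenes)
    f_true = pd.DataFrame(F, index=patients, columns=cells)
    return gtab, sig, f_true
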