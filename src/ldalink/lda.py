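"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Patients are documents and genes (or microbes) are words; the scaled
integer abundance of entity v in patient p is the number of tokens of
word v in document p.  With symmetric Dirichlet priors alpha (over the
N_k topics of each document) and beta (over the N_v words of each topic)
the topic indicators Z are sampled from their collapsed full conditional

    P(z = k | Z_-, W)  propto  (n_{k,v}^- + beta) / (n_k^- + N_v beta)
                               * (n_{p,k}^- + alpha)

where the "-" counts exclude the token being resampled.  After sampling,
posterior-mean estimates of the document-topic matrix theta and the
topic-word matrix phi are read off the smoothed counts:

    theta_{p,k} = (n_{p,k} + alpha) / (n_p + N_k alpha)
    phi_{k,v}   = (n_{k,v} + beta)  / (n_k + N_v beta)

The inner sweep is a numba kernel; all randomness is drawn from a numpy
Generator outside the kernel, so a fit is bit-reproducible under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

__all__ = [
    "LDAConfig",
    "LDAState",
    "LDAModel",
    "init_state",
    "gibbs_sweep",
    "token_conditional",
    "estimate",
    "fit_lda",
    "log_joint",
]

logger = logging.getLogger(__name__)


@dataclass
class LDAConfig:
    """Sampler configuration.

    ``n_topics`` defaults to 10, the dimensionality used throughout the
    link-prediction pipeline.  ``alpha``/``beta`` are the symmetric
    Dirichlet hyper-parameters over topics-in-document and
    words-in-topic; smaller values give sparser decompositions.
    """

    n_topics: int = 10
    alpha: float = 0.5
    beta: float = 0.1
    n_sweeps: int = 1000
    burn_in: int = 500
    seed: int = 0
    #: "final" estimates theta/phi from the last state; "average" averages
    #: the estimators over all post-burn-in sweeps.
    estimate_mode: str = "final"

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.burn_in >= self.n_sweeps:
            raise ValueError("burn_in must be smaller than n_sweeps")
        if self.estimate_mode not in ("final", "average"):
            raise ValueError("estimate_mode must be 'final' or 'average'")


@dataclass
class LDAState:
    """Token-level sampler state and its sufficient count statistics."""

    doc_of_token: np.ndarray  # int32, token -> document index
    word_of_token: np.ndarray  # int32, token -> vocabulary index
    z: np.ndarray  # int32, token -> topic in [0, n_topics)
    n_doc_topic: np.ndarray  # (N_p, N_k)
    n_topic_word: np.ndarray  # (N_k, N_v)
    n_topic_total: np.ndarray  # (N_k,)
    doc_ids: list[str]
    vocab: list[str]

    @property
    def n_tokens(self) -> int:
        return self.z.shape[0]

    @property
    def doc_lengths(self) -> np.ndarray:
        return self.n_doc_topic.sum(axis=1)

    def check_consistency(self) -> None:
        """Assert count matrices agree with the token-level assignment."""
        n_docs, n_topics = self.n_doc_topic.shape
        ndt = np.zeros_like(self.n_doc_topic)
        ntw = np.zeros_like(self.n_topic_word)
        np.add.at(ndt, (self.doc_of_token, self.z), 1)
        np.add.at(ntw, (self.z, self.word_of_token), 1)
        if not np.array_equal(ndt, self.n_doc_topic):
            raise AssertionError("n_doc_topic inconsistent with z")
        if not np.array_equal(ntw, self.n_topic_word):
            raise AssertionError("n_topic_word inconsistent with z")
        if not np.array_equal(self.n_topic_word.sum(axis=1), self.n_topic_total):
            raise AssertionError("n_topic_total inconsistent with n_topic_word")


@dataclass
class LDAModel:
    """Posterior-mean estimates with patient/word identifiers attached."""

    theta: pd.DataFrame  # patients x topics
    phi: pd.DataFrame  # topics x words
    config: LDAConfig
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    @property
    def vocab(self) -> list[str]:
        return list(self.phi.columns)


def init_state(counts, config: LDAConfig, rng: np.random.Generator | None = None) -> LDAState:
    """Expand integer counts to tokens and assign topics uniformly at random.

    Documents with zero tokens after scaling carry no information for the
    sampler; they are dropped with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    values = counts.values
    doc_ids = list(counts.row_ids)
    vocab = list(counts.col_ids)
    if values.sum() == 0:
        raise ValueError("empty corpus: all counts are zero")
    keep = values.sum(axis=1) > 0
    if not keep.all():
        dropped = [doc_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d all-zero documents: %s", len(dropped), dropped[:5])
        values = values[keep]
        doc_ids = [d for d, k in zip(doc_ids, keep) if k]

    docs, words = np.nonzero(values)
    reps = values[docs, words]
    doc_of_token = np.repeat(docs, reps).astype(np.int32)
    word_of_token = np.repeat(words, reps).astype(np.int32)
    z = rng.integers(0, config.n_topics, size=doc_of_token.shape[0]).astype(np.int32)

    n_doc_topic = np.zeros((len(doc_ids), config.n_topics), dtype=np.int64)
    n_topic_word = np.zeros((config.n_topics, len(vocab)), dtype=np.int64)
    np.add.at(n_doc_topic, (doc_of_token, z), 1)
    np.add.at(n_topic_word, (z, word_of_token), 1)
    return LDAState(
        doc_of_token=doc_of_token,
        word_of_token=word_of_token,
        z=z,
        n_doc_topic=n_doc_topic,
        n_topic_word=n_topic_word,
        n_topic_total=n_topic_word.sum(axis=1),
        doc_ids=doc_ids,
        vocab=vocab,
    )


@njit(cache=True)
def _sweep_kernel(doc_of_token, word_of_token, z, n_doc_topic, n_topic_word,
                  n_topic_total, alpha, beta, uniforms):  # pragma: no cover
    n_tokens = z.shape[0]
    n_topics = n_doc_topic.shape[1]
    n_vocab = n_topic_word.shape[1]
    cum = np.empty(n_topics, dtype=np.float64)
    vbeta = n_vocab * beta
    for i in range(n_tokens):
        d = doc_of_token[i]
        v = word_of_token[i]
        k_old = z[i]
        n_doc_topic[d, k_old] -= 1
        n_topic_word[k_old, v] -= 1
        n_topic_total[k_old] -= 1
        total = 0.0
        for k in range(n_topics):
            total += (n_topic_word[k, v] + beta) / (n_topic_total[k] + vbeta) * (
                n_doc_topic[d, k] + alpha
            )
            cum[k] = total
        r = uniforms[i] * total
        k_new = 0
        while cum[k_new] < r and k_new < n_topics - 1:
            k_new += 1
        z[i] = k_new
        n_doc_topic[d, k_new] += 1
        n_topic_word[k_new, v] += 1
        n_topic_total[k_new] += 1


def gibbs_sweep(state: LDAState, config: LDAConfig, rng: np.random.Generator) -> LDAState:
    """Resample every token once, document-major / token-minor, in place."""
    uniforms = rng.random(state.n_tokens)
    _sweep_kernel(
        state.doc_of_token,
        state.word_of_token,
        state.z,
        state.n_doc_topic,
        state.n_topic_word,
        state.n_topic_total,
        float(config.alpha),
        float(config.beta),
        uniforms,
    )
    return state


def token_conditional(state: LDAState, config: LDAConfig, token: int) -> np.ndarray:
    """Normalized full-conditional topic distribution for one token.

    Computed from the count matrices with the token's own count excluded;
    the sweep kernel draws from exactly this distribution.
    """
    d = state.doc_of_token[token]
    v = state.word_of_token[token]
    k_old = state.z[token]
    ndt = state.n_doc_topic[d].astype(float).copy()
    ntw = state.n_topic_word[:, v].astype(float).copy()
    nt = state.n_topic_total.astype(float).copy()
    ndt[k_old] -= 1
    ntw[k_old] -= 1
    nt[k_old] -= 1
    n_vocab = state.n_topic_word.shape[1]
    p = (ntw + config.beta) / (nt + n_vocab * config.beta) * (ndt + config.alpha)
    return p / p.sum()


def log_joint(state: LDAState, config: LDAConfig) -> float:
    """Collapsed log joint log P(Z, W; alpha, beta) of the current state.

    Product over topics of Delta(n_{.,k} + beta)/Delta(beta) times the
    product over documents of Delta(n_{p,.} + alpha)/Delta(alpha), where
    Delta is the multivariate beta function.
    """
    n_topics = config.n_topics
    n_vocab = state.n_topic_word.shape[1]
    a, b = config.alpha, config.beta
    word_part = (
        gammaln(state.n_topic_word + b).sum()
        - gammaln(state.n_topic_total + n_vocab * b).sum()
        - n_topics * (n_vocab * gammaln(b) - gammaln(n_vocab * b))
    )
    doc_lengths = state.n_doc_topic.sum(axis=1)
    doc_part = (
        gammaln(state.n_doc_topic + a).sum()
        - gammaln(doc_lengths + n_topics * a).sum()
        - len(state.doc_ids) * (n_topics * gammaln(a) - gammaln(n_topics * a))
    )
    return float(word_part + doc_part)


def estimate(state: LDAState, config: LDAConfig) -> LDAModel:
    """theta and phi from the smoothed counts of the current state."""
    a, b = config.alpha, config.beta
    n_topics = config.n_topics
    n_vocab = state.n_topic_word.shape[1]
    theta = (state.n_doc_topic + a) / (
        state.n_doc_topic.sum(axis=1, keepdims=True) + n_topics * a
    )
    phi = (state.n_topic_word + b) / (
        state.n_topic_word.sum(axis=1, keepdims=True) + n_vocab * b
    )
    return LDAModel(
        theta=pd.DataFrame(theta, index=state.doc_ids,
                           columns=[f"topic_{k}" for k in range(n_topics)]),
        phi=pd.DataFrame(phi, index=[f"topic_{k}" for k in range(n_topics)],
                         columns=state.vocab),
        config=config,
    )


def fit_lda(counts, config: LDAConfig, track_likelihood: bool = True) -> LDAModel:
    """Run the full sampler: init, ``n_sweeps`` sweeps, then estimate.

    Topics in the returned model are relabeled in descending order of
    total mass so repeated fits are comparable; label switching across
    seeds is still expected and handled by permutation matching in
    evaluations.
    """
    rng = np.random.default_rng(config.seed)
    state = init_state(counts, config, rng)
    total_tokens = state.n_tokens
    trace: list[float] = []
    theta_acc = np.zeros_like(state.n_doc_topic, dtype=float)
    phi_acc = np.zeros_like(state.n_topic_word, dtype=float)
    n_acc = 0
    for sweep in range(config.n_sweeps):
        gibbs_sweep(state, config, rng)
        if track_likelihood:
            trace.append(log_joint(state, config))
        if config.estimate_mode == "average" and sweep >= config.burn_in:
            m = estimate(state, config)
            theta_acc += m.theta.to_numpy()
            phi_acc += m.phi.to_numpy()
            n_acc += 1
    assert state.n_tokens == total_tokens

    model = estimate(state, config)
    if config.estimate_mode == "average" and n_acc > 0:
        model.theta.iloc[:, :] = theta_acc / n_acc
        model.phi.iloc[:, :] = phi_acc / n_acc
    # canonical topic order: descending total mass
    mass = state.n_topic_total
    order = np.argsort(-mass, kind="stable")
    topic_names = [f"topic_{k}" for k in range(config.n_topics)]
    model.theta = pd.DataFrame(model.theta.to_numpy()[:, order],
                               index=model.theta.index, columns=topic_names)
    model.phi = pd.DataFrame(model.phi.to_numpy()[order, :],
                             index=topic_names, columns=model.phi.columns)
    model.log_likelihood_trace = trace
    return model
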