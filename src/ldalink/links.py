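"""Self-supervised gene-microbe link prediction (LDA-link).

Strong linear correlations between gene expression and microbe abundance
are rare but trustworthy; this module uses them as a pseudo-gold
standard.  Pairs with |r| above a threshold at a stringent p-value
become positive labels, an equal-sized random sample of near-zero
correlations the negatives.  Each pair is then featurized not by the raw
profiles but by the topic space: the gene's topic-weight column of the
gene LDA model concatenated with the microbe's topic-weight column of
the microbe LDA model (length 2 * N_k, 20 at the default ten topics).
A random forest trained on these features generalizes beyond linear
dependence, and is validated by a strict left-out protocol in which held
out pairs share no gene and no microbe with the training pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .correlate import CorrelationResult
from .lda import LDAModel

__all__ = [
    "TrainingSet",
    "LinkTable",
    "CVReport",
    "build_pseudo_gold",
    "make_features",
    "feature_matrix",
    "train_link_model",
    "strict_leftout_cv",
    "predict_links",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass
class TrainingSet:
    """Labeled gene-microbe pairs with the thresholds that produced them."""

    positives: list[Pair]
    negatives: list[Pair]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:3]}")

    @property
    def pairs(self) -> list[Pair]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))


@dataclass
class LinkTable:
    """Predicted link probabilities for all scored gene-microbe pairs."""

    table: pd.DataFrame  # gene, microbe, probability, is_training, is_high_confidence
    threshold: float = 0.95

    @property
    def high_confidence(self) -> pd.DataFrame:
        return self.table[self.table["is_high_confidence"]]


@dataclass
class CVReport:
    aucs: list[float]
    pooled_fpr: np.ndarray
    pooled_tpr: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def build_pseudo_gold(
    cor: CorrelationResult,
    r_pos: float = 0.4,
    p_pos: float = 1e-5,
    r_neg: float = 0.05,
    seed: int = 0,
) -> TrainingSet:
    """Label pairs from the correlation screen.

    Positives: |r| > ``r_pos`` and p < ``p_pos``.  Negatives: a seeded
    uniform sample, of the same size, from pairs with |r| < ``r_neg``.
    """
    r = cor.r.to_numpy()
    p = cor.p.to_numpy()
    genes = list(cor.r.index)
    microbes = list(cor.r.columns)
    with np.errstate(invalid="ignore"):
        pos_mask = (np.abs(r) > r_pos) & (p < p_pos)
        neg_mask = np.abs(r) < r_neg
    positives = [(genes[i], microbes[j]) for i, j in np.argwhere(pos_mask)]
    if not positives:
        raise ValueError(
            f"no pairs pass |r| > {r_pos}, p < {p_pos}; review thresholds"
        )
    neg_pool = np.argwhere(neg_mask)
    if len(neg_pool) < len(positives):
        raise ValueError(
            f"only {len(neg_pool)} near-zero pairs available for "
            f"{len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(neg_pool), size=len(positives), replace=False)
    negatives = [(genes[i], microbes[j]) for i, j in neg_pool[np.sort(take)]]
    logger.info("pseudo-gold standard: %d positives, %d negatives",
                len(positives), len(negatives))
    return TrainingSet(
        positives=positives,
        negatives=negatives,
        provenance={"r_pos": r_pos, "p_pos": p_pos, "r_neg": r_neg, "seed": seed},
    )


def _entity_features(model: LDAModel, normalize: bool) -> pd.DataFrame:
    """Per-entity topic columns of phi (topics x entities -> entities x topics)."""
    cols = model.phi.T
    if normalize:
        cols = cols.div(cols.sum(axis=1), axis=0)
    return cols


def make_features(
    phiG: LDAModel,
    phiM: LDAModel,
    pair: Pair,
    normalize: bool = True,
) -> np.ndarray:
    """Feature vector for one pair: gene topic column then microbe topic column.

    With ``normalize`` (default) each entity's phi column is L1-normalized
    so rare and abundant entities are comparable; each half of the vector
    then sums to one.
    """
    gene, microbe = pair
    if gene not in phiG.phi.columns:
        raise KeyError(f"gene {gene!r} not in the gene topic model vocabulary")
    if microbe not in phiM.phi.columns:
        raise KeyError(f"microbe {microbe!r} not in the microbe topic model vocabulary")
    g = phiG.phi[gene].to_numpy(dtype=float)
    m = phiM.phi[microbe].to_numpy(dtype=float)
    if normalize:
        g = g / g.sum()
        m = m / m.sum()
    return np.concatenate([g, m])


def feature_matrix(
    phiG: LDAModel,
    phiM: LDAModel,
    pairs: list[Pair],
    normalize: bool = True,
) -> np.ndarray:
    """Vectorized feature construction for a list of pairs."""
    gfeat = _entity_features(phiG, normalize)
    mfeat = _entity_features(phiM, normalize)
    missing_g = {g for g, _ in pairs} - set(gfeat.index)
    missing_m = {m for _, m in pairs} - set(mfeat.index)
    if missing_g or missing_m:
        raise KeyError(f"entities missing from topic models: "
                       f"genes {sorted(missing_g)[:3]}, microbes {sorted(missing_m)[:3]}")
    gm = gfeat.loc[[g for g, _ in pairs]].to_numpy(dtype=float)
    mm = mfeat.loc[[m for _, m in pairs]].to_numpy(dtype=float)
    return np.hstack([gm, mm])


def _feature_names(n_topics: int) -> list[str]:
    return [f"gene topic {k}" for k in range(n_topics)] + [
        f"microbe topic {k}" for k in range(n_topics)
    ]


def train_link_model(
    ts: TrainingSet,
    phiG: LDAModel,
    phiM: LDAModel,
    n_trees: int = 500,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[RandomForestClassifier, pd.Series]:
    """Random-forest link classifier plus labeled Gini importances."""
    if not ts.positives or not ts.negatives:
        raise ValueError("training set must contain both classes")
    X = feature_matrix(phiG, phiM, ts.pairs, normalize)
    y = ts.labels
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1,
    )
    model.fit(X, y)
    importances = pd.Series(model.feature_importances_,
                            index=_feature_names(phiG.n_topics),
                            name="gini_importance")
    return model, importances


def strict_leftout_cv(
    ts: TrainingSet,
    phiG: LDAModel,
    phiM: LDAModel,
    test_frac: float = 0.10,
    n_repeats: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    normalize: bool = True,
    max_retries: int = 20,
) -> CVReport:
    """Strict left-out cross-validation of the link classifier.

    Per repeat, ``test_frac`` of the labeled pairs are held out and every
    remaining pair that shares a gene OR a microbe with the held-out set
    is discarded from training (leaving slightly less than the nominal
    complement).  Entity disjointness between train and test is asserted.
    A repeat whose entity removal empties a class is resampled (bounded).
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    pairs = ts.pairs
    labels = ts.labels
    n_test = max(1, int(round(test_frac * len(pairs))))
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for rep in range(n_repeats):
        for attempt in range(max_retries):
            test_idx = rng.choice(len(pairs), size=n_test, replace=False)
            test_set = set(test_idx.tolist())
            test_genes = {pairs[i][0] for i in test_idx}
            test_microbes = {pairs[i][1] for i in test_idx}
            train_idx = [
                i for i in range(len(pairs))
                if i not in test_set
                and pairs[i][0] not in test_genes
                and pairs[i][1] not in test_microbes
            ]
            y_train = labels[train_idx]
            y_test = labels[test_idx]
            if len(set(y_train)) == 2 and len(set(y_test)) == 2:
                break
            logger.info("repeat %d attempt %d: degenerate split, resampling", rep, attempt)
        else:
            raise RuntimeError("could not draw a non-degenerate strict split")

        train_genes = {pairs[i][0] for i in train_idx}
        train_microbes = {pairs[i][1] for i in train_idx}
        assert not (train_genes & test_genes), "gene leakage between train and test"
        assert not (train_microbes & test_microbes), "microbe leakage between train and test"

        sub = TrainingSet(
            positives=[pairs[i] for i in train_idx if labels[i] == 1],
            negatives=[pairs[i] for i in train_idx if labels[i] == 0],
        )
        model, _ = train_link_model(sub, phiG, phiM, n_trees=n_trees,
                                    seed=int(rng.integers(2**31)), normalize=normalize)
        X_test = feature_matrix(phiG, phiM, [pairs[i] for i in test_idx], normalize)
        scores = model.predict_proba(X_test)[:, 1]
        aucs.append(float(roc_auc_score(y_test, scores)))
        pooled_scores.append(scores)
        pooled_labels.append(y_test)
    fpr, tpr, _ = roc_curve(np.concatenate(pooled_labels), np.concatenate(pooled_scores))
    return CVReport(aucs=aucs, pooled_fpr=fpr, pooled_tpr=tpr)


def predict_links(
    model: RandomForestClassifier,
    phiG: LDAModel,
    phiM: LDAModel,
    ts: TrainingSet,
    hi_cut: float = 0.95,
    normalize: bool = True,
    exclude_training_entities: bool = False,
) -> LinkTable:
    """Score every non-training gene-microbe pair.

    Training pairs are excluded exactly (``exclude_training_entities``
    widens the exclusion to any pair touching a training gene or
    microbe).  A link is high confidence when probability > ``hi_cut``
    (strict).  Output sorted by descending probability, ties broken by
    (gene, microbe) lexicographic order.
    """
    genes = list(phiG.phi.columns)
    microbes = list(phiM.phi.columns)
    training = set(ts.pairs)
    if exclude_training_entities:
        tg = {g for g, _ in training}
        tm = {m for _, m in training}
        pairs = [(g, m) for g in genes for m in microbes if g not in tg and m not in tm]
    else:
        pairs = [(g, m) for g in genes for m in microbes if (g, m) not in training]
    if pairs:
        X = feature_matrix(phiG, phiM, pairs, normalize)
        probs = model.predict_proba(X)[:, 1]
    else:
        probs = np.empty(0)
    frame = pd.DataFrame({
        "gene": [g for g, _ in pairs],
        "microbe": [m for _, m in pairs],
        "probability": probs,
        "is_training": False,
        "is_high_confidence": probs > hi_cut,
    })
    frame = frame.sort_values(
        ["probability", "gene", "microbe"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return LinkTable(table=frame, threshold=hi_cut)
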