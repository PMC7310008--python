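"""Pseudo-gold construction, pair features, classifier, strict CV."""

import numpy as np
import pandas as pd
import pytest

from ldalink.correlate import CorrelationResult, correlate_tables
from ldalink.lda import LDAConfig, LDAModel
from ldalink.links import (
    TrainingSet,
    build_pseudo_gold,
    feature_matrix,
    make_features,
    predict_links,
    strict_leftout_cv,
    train_link_model,
)
from ldalink.synthetic import gen_linked_tables


def phi_model(phi: np.ndarray, entities: list[str]) -> LDAModel:
    """Hand-built topic model with the given topics x entities matrix."""
    k = phi.shape[0]
    frame = pd.DataFrame(phi, index=[f"topic_{i}" for i in range(k)], columns=entities)
    theta = pd.DataFrame(index=[], columns=frame.index)
    return LDAModel(theta=theta, phi=frame, config=LDAConfig(n_topics=k, n_sweeps=2,
                                                             burn_in=1))


@pytest.fixture
def toy_models(rng):
    """Ten genes and ten microbes, entity e loading mostly on topic e % 5."""
    k = 5
    genes = [f"G{i}" for i in range(10)]
    microbes = [f"m{i}" for i in range(10)]

    def build(names):
        phi = np.full((k, len(names)), 0.01)
        for i in range(len(names)):
            phi[i % k, i] = 1.0
        phi /= phi.sum(axis=1, keepdims=True)
        return phi

    return phi_model(build(genes), genes), phi_model(build(microbes), microbes)


@pytest.fixture(scope="module")
def planted_cor():
    G, M, truth = gen_linked_tables(
        n_patients=115, n_genes=100, n_microbes=50, n_linear_links=30,
        n_threshold_links=0, seed=9)
    return correlate_tables(G, M), truth


class TestBuildPseudoGold:
    def test_planted_strong_pairs_recovered(self, planted_cor):
        cor, truth = planted_cor
        ts = build_pseudo_gold(cor, seed=0)
        planted = [(g, m) for g, m, _ in truth.planted_links]
        recovered = sum(p in set(ts.positives) for p in planted)
        assert recovered >= 27
        assert len(ts.negatives) == len(ts.positives)

    def test_impossible_threshold_errors(self, planted_cor):
        cor, _ = planted_cor
        with pytest.raises(ValueError, match="review"):
            build_pseudo_gold(cor, r_pos=1.0)

    def test_negative_sample_deterministic(self, planted_cor):
        cor, _ = planted_cor
        a = build_pseudo_gold(cor, seed=3)
        b = build_pseudo_gold(cor, seed=3)
        assert a.negatives == b.negatives

    def test_overlapping_labels_rejected(self):
        with pytest.raises(ValueError, match="both"):
            TrainingSet(positives=[("G1", "m1")], negatives=[("G1", "m1")])


class TestMakeFeatures:
    def test_length_is_twice_topics(self, toy_models):
        phiG, phiM = toy_models
        feats = make_features(phiG, phiM, ("G0", "m0"))
        assert feats.shape == (10,)  # 2 * 5 topics

    def test_degenerate_column_is_indicator(self, toy_models):
        phiG, phiM = toy_models
        phi = phiG.phi.copy()
        phi["G0"] = 0.0
        phi.loc["topic_3", "G0"] = 0.42
        feats = make_features(phi_model(phi.to_numpy(), list(phi.columns)), phiM,
                              ("G0", "m0"))
        np.testing.assert_allclose(feats[:5], [0, 0, 0, 1, 0])

    def test_swapping_entities_swaps_halves(self, toy_models):
        phiG, phiM = toy_models
        shared = phi_model(phiG.phi.to_numpy(), list(phiG.phi.columns))
        a = make_features(phiG, shared, ("G1", "G2"))
        b = make_features(phiG, shared, ("G2", "G1"))
        np.testing.assert_allclose(a[:5], b[5:])
        np.testing.assert_allclose(a[5:], b[:5])

    def test_unknown_entity_named(self, toy_models):
        phiG, phiM = toy_models
        with pytest.raises(KeyError, match="nope"):
            make_features(phiG, phiM, ("nope", "m0"))

    def test_halves_sum_to_one(self, toy_models, rng):
        phiG, phiM = toy_models
        feats = feature_matrix(phiG, phiM, [("G3", "m7"), ("G2", "m2")])
        np.testing.assert_allclose(feats[:, :5].sum(axis=1), 1.0)
        np.testing.assert_allclose(feats[:, 5:].sum(axis=1), 1.0)


def separable_training_set(n_per_class=60, k=5, seed=0):
    """Positives are (gene, microbe) pairs where BOTH entities load on topic
    1; negatives reuse topic-1 entities on one side only, so neither half of
    the feature vector separates the classes alone."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(2 * n_per_class)]
    microbes = [f"m{i}" for i in range(2 * n_per_class)]

    def topics(half_on_one):
        first = [1] * half_on_one
        rest = [int(t) for t in rng.integers(2, k, 2 * n_per_class - half_on_one)]
        return first + rest

    def build(names, assigned):
        phi = np.full((k, len(names)), 0.02)
        for i, name in enumerate(names):
            phi[assigned[i], i] += 1.0 + 0.1 * rng.random()
        phi /= phi.sum(axis=1, keepdims=True)
        return phi

    # 1.5 classes worth of topic-1 entities: half the negatives can reuse them
    gene_topics = topics(3 * n_per_class // 2)
    microbe_topics = topics(3 * n_per_class // 2)
    phiG = phi_model(build(genes, gene_topics), genes)
    phiM = phi_model(build(microbes, microbe_topics), microbes)
    positives = [(genes[i], microbes[i]) for i in range(n_per_class)]
    negatives = []
    for i in range(n_per_class):  # alternate which side carries topic 1
        if i % 2 == 0:
            negatives.append((genes[n_per_class + i // 2],
                              microbes[2 * n_per_class - 1 - i // 2]))
        else:
            negatives.append((genes[2 * n_per_class - 1 - i // 2],
                              microbes[n_per_class + i // 2]))
    return phiG, phiM, TrainingSet(positives=positives, negatives=negatives)


class TestTrainLinkModel:
    def test_separable_classes_learned(self):
        phiG, phiM, ts = separable_training_set()
        model, importances = train_link_model(ts, phiG, phiM, n_trees=200, seed=1)
        X = feature_matrix(phiG, phiM, ts.pairs)
        acc = (model.predict(X) == ts.labels).mean()
        assert acc >= 0.95
        top3 = set(importances.nlargest(3).index)
        assert {"gene topic 1", "microbe topic 1"} <= top3

    def test_shuffled_labels_near_chance(self, rng):
        phiG, phiM, ts = separable_training_set()
        labels = ts.labels.copy()
        rng.shuffle(labels)
        shuffled = TrainingSet(
            positives=[p for p, y in zip(ts.pairs, labels) if y == 1],
            negatives=[p for p, y in zip(ts.pairs, labels) if y == 0])
        model, _ = train_link_model(shuffled, phiG, phiM, n_trees=200, seed=1)
        assert abs(model.oob_score_ - 0.5) <= 0.12

    def test_single_class_rejected(self, toy_models):
        phiG, phiM = toy_models
        with pytest.raises(ValueError, match="both classes"):
            train_link_model(TrainingSet(positives=[("G0", "m0")], negatives=[]),
                             phiG, phiM)

    def test_seed_determinism(self):
        phiG, phiM, ts = separable_training_set()
        m1, _ = train_link_model(ts, phiG, phiM, n_trees=100, seed=7)
        m2, _ = train_link_model(ts, phiG, phiM, n_trees=100, seed=7)
        X = feature_matrix(phiG, phiM, ts.pairs)
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))


class TestStrictLeftoutCV:
    def test_entity_disjointness_is_asserted_and_auc_high(self):
        # disjointness is a hard assertion inside every repeat
        phiG, phiM, ts = separable_training_set(n_per_class=80)
        report = strict_leftout_cv(ts, phiG, phiM, n_repeats=5, n_trees=100, seed=2)
        assert len(report.aucs) == 5
        assert report.mean_auc >= 0.8

    def test_zero_test_frac_rejected(self):
        phiG, phiM, ts = separable_training_set()
        with pytest.raises(ValueError, match="test_frac"):
            strict_leftout_cv(ts, phiG, phiM, test_frac=0.0)


class TestPredictLinks:
    def test_training_pairs_excluded_and_sorted(self):
        phiG, phiM, ts = separable_training_set(n_per_class=30)
        model, _ = train_link_model(ts, phiG, phiM, n_trees=100, seed=0)
        lt = predict_links(model, phiG, phiM, ts)
        scored = set(zip(lt.table.gene, lt.table.microbe))
        assert not scored & set(ts.pairs)
        probs = lt.table.probability.to_numpy()
        assert (np.diff(probs) <= 1e-12).all()

    def test_hi_cut_one_gives_no_high_confidence(self):
        phiG, phiM, ts = separable_training_set(n_per_class=30)
        model, _ = train_link_model(ts, phiG, phiM, n_trees=100, seed=0)
        lt = predict_links(model, phiG, phiM, ts, hi_cut=1.0)
        assert lt.high_confidence.empty

    def test_entity_level_exclusion_option(self):
        phiG, phiM, full = separable_training_set(n_per_class=30)
        ts = TrainingSet(positives=full.positives[:10], negatives=full.negatives[:10])
        model, _ = train_link_model(ts, phiG, phiM, n_trees=100, seed=0)
        lt = predict_links(model, phiG, phiM, ts, exclude_training_entities=True)
        assert len(lt.table) > 0
        train_genes = {g for g, _ in ts.pairs}
        train_microbes = {m for _, m in ts.pairs}
        assert not set(lt.table.gene) & train_genes
        assert not set(lt.table.microbe) & train_microbes
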