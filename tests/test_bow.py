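"""Bag-of-words vocabulary, featurization, classifiers, cross-validation."""

import numpy as np
import pytest

from sleepscan.bow import (
    BowClassifier,
    build_vocab,
    cross_validate,
    featurize,
    featurize_batch,
    train_bow,
)
from sleepscan.segmenter import Candidate, Label


def cand(window, value=1.0, label=Label.OTHER, report_id="R1", left=1, top=1,
         width=10, height=10, page=1, idx=0):
    return Candidate(report_id=report_id, token=str(value), value=value, left=left,
                     top=top, width=width, height=height, page_num=page,
                     order_idx=idx, window=tuple(window), label=label)


class TestVocab:
    def test_top_400_cap(self):
        windows = [[f"term{i:03d}"] * 2 for i in range(450)]
        vocab = build_vocab(windows)
        assert len(vocab.terms) == 400

    def test_small_corpus_keeps_all_terms(self):
        vocab = build_vocab([["apnea", "index"], ["apnea", "saturation", "nadir"]])
        assert set(vocab.terms) == {"apnea", "index", "saturation", "nadir"}

    def test_stopwords_never_in_vocab(self):
        vocab = build_vocab([["the", "was", "apnea", "The"]])
        assert "the" not in vocab.terms and "was" not in vocab.terms

    def test_frequency_ranking_with_lexicographic_ties(self):
        windows = [["zebra", "zebra", "alpha", "beta"]]
        vocab = build_vocab(windows, max_terms=2)
        assert vocab.terms == ("zebra", "alpha")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_vocab([])

    def test_no_leakage_from_nontraining_windows(self):
        train = [["apnea", "index"]] * 3
        v1 = build_vocab(train)
        v2 = build_vocab(train)  # rebuilding never sees test data at all
        assert v1.terms == v2.terms and np.allclose(v1.idf, v2.idf)


class TestFeaturize:
    def test_structured_block_from_published_row(self):
        c = cand(["x"], value=19.5, left=1048, top=385, width=111, height=50, page=1)
        fv = featurize(c, build_vocab([["apnea"]]))
        assert tuple(fv.structured) == (1048.0, 385.0, 111.0, 50.0, 1.0, 19.5)

    def test_tfidf_unit_norm_when_terms_present(self):
        vocab = build_vocab([["apnea", "index", "nadir"]] * 2)
        fv = featurize(cand(["apnea", "apnea", "index"]), vocab)
        assert np.isclose(np.linalg.norm(fv.tfidf), 1.0)

    def test_zero_block_when_no_vocab_terms(self):
        vocab = build_vocab([["apnea"]])
        fv = featurize(cand(["saturation", "only"]), vocab)
        assert np.linalg.norm(fv.tfidf) == 0.0

    def test_total_dimension(self):
        vocab = build_vocab([["a1", "b2", "c3"]])
        X = featurize_batch([cand(["a1"])], vocab)
        assert X.shape == (1, 6 + len(vocab.terms))

    def test_deterministic_given_vocab(self):
        vocab = build_vocab([["apnea", "index"]] * 2)
        c = cand(["apnea", "index", "extra"])
        assert np.array_equal(featurize(c, vocab).vector, featurize(c, vocab).vector)


def _separable_data(n_per_class=20, seed=0):
    """3 linearly separable clusters in the structured block."""
    rng = np.random.default_rng(seed)
    cands, labels = [], []
    centers = {Label.AHI: 0.0, Label.SAO2: 300.0, Label.OTHER: 600.0}
    for lab, base in centers.items():
        for i in range(n_per_class):
            cands.append(
                cand(["apnea"], value=base + rng.uniform(0, 20), label=lab,
                     left=int(base) + i, top=int(base), idx=i,
                     report_id=f"R{lab.value}{i % 10}")
            )
            labels.append(lab)
    return cands, labels


class TestClassifiers:
    @pytest.mark.parametrize("clf", [BowClassifier.RF, BowClassifier.KNN])
    def test_separable_fixture_training_accuracy(self, clf):
        cands, labels = _separable_data()
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        model = train_bow(X, labels, clf, vocab,
                          params={"n_estimators": 50} if clf is BowClassifier.RF else None)
        pred = model.predict(X)
        assert np.mean([p == t for p, t in zip(pred, labels)]) == 1.0

    def test_knn_majority_rule(self):
        cands, labels = _separable_data(n_per_class=5)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        model = train_bow(X, labels, BowClassifier.KNN, vocab)
        probe = featurize_batch([cand(["apnea"], value=5.0, left=2, top=0)], vocab)
        assert model.predict(probe) == [Label.AHI]

    def test_nb_smoothing_gives_nonzero_probabilities(self):
        cands, labels = _separable_data(n_per_class=8)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        model = train_bow(X, labels, BowClassifier.NB, vocab)
        probe = featurize_batch([cand(["unseen"], value=1.0)], vocab)
        proba = model.predict_proba(probe)
        assert (proba > 0).all()

    def test_single_class_rejected(self):
        cands, _ = _separable_data(n_per_class=4)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        with pytest.raises(ValueError, match="2 classes"):
            train_bow(X, [Label.AHI] * len(cands), BowClassifier.LR, vocab)

    @pytest.mark.parametrize("clf", list(BowClassifier))
    def test_all_seven_produce_valid_probabilities(self, clf):
        cands, labels = _separable_data(n_per_class=10)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        params = {"n_estimators": 30} if clf is BowClassifier.RF else None
        model = train_bow(X, labels, clf, vocab, params=params)
        proba = model.predict_proba(X)
        assert proba.shape == (len(cands), 3)
        assert (proba >= 0).all() and (proba <= 1).all()


class TestCrossValidate:
    def test_single_point_grid(self):
        cands, labels = _separable_data(n_per_class=12)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        rids = [c.report_id for c in cands]
        best, model, accs = cross_validate(X, labels, rids, BowClassifier.KNN,
                                           [{"n_neighbors": 3}], vocab, k=5, seed=0)
        assert best == {"n_neighbors": 3} and len(accs) == 1

    def test_selection_matches_bruteforce_fold_accounting(self):
        cands, labels = _separable_data(n_per_class=12, seed=3)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        rids = [c.report_id for c in cands]
        grid = [{"n_neighbors": 1}, {"n_neighbors": 3}, {"n_neighbors": 5}]
        best, _, accs = cross_validate(X, labels, rids, BowClassifier.KNN, grid, vocab,
                                       k=5, seed=7)

        # independent brute-force recomputation of the same fold accuracies
        from sleepscan.bow import train_bow as tb

        uniq = np.unique(rids)
        order = np.random.default_rng(7).permutation(len(uniq))
        folds = np.array_split(uniq[order], 5)
        expected = []
        for params in grid:
            fold_accs = []
            for fold in folds:
                mask = np.isin(rids, fold)
                m = tb(X[~mask], [l for l, s in zip(labels, mask) if not s],
                       BowClassifier.KNN, vocab, params)
                pred = m.predict(X[mask])
                truth = [l for l, s in zip(labels, mask) if s]
                fold_accs.append(np.mean([p == t for p, t in zip(pred, truth)]))
            expected.append(np.mean(fold_accs))
        assert np.allclose(accs, expected)
        assert best == grid[int(np.argmax(expected))]

    def test_folds_partition_reports(self):
        rids = np.array([f"R{i}" for i in range(20)])
        order = np.random.default_rng(3).permutation(20)
        folds = np.array_split(rids[order], 5)
        seen = [r for f in folds for r in f]
        assert sorted(seen) == sorted(rids)

    def test_empty_grid_rejected(self):
        cands, labels = _separable_data(n_per_class=6)
        vocab = build_vocab([c.window for c in cands])
        X = featurize_batch(cands, vocab)
        with pytest.raises(ValueError, match="grid"):
            cross_validate(X, labels, [c.report_id for c in cands],
                           BowClassifier.KNN, [], vocab)
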