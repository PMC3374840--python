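import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mksubloc import (
    FeatureViews,
    KernelBundle,
    LabelTable,
    VIEW_NAMES,
    apply_scenario,
    build_vocabularies,
    combine,
    encode_views,
    estimate_weights,
    gaussian_gram,
)
from mksubloc.kernels import _stratify_folds
from mksubloc.evaluation import locative_expand
from mksubloc.mlsvm import predict_proba, rank_assign_locative, train_ova


class TestGaussianGram:
    def test_identical_rows_give_one(self):
        x = np.array([[1, 0, 1, 1]])
        assert gaussian_gram(x, x, gamma=0.7)[0, 0] == pytest.approx(1.0)

    def test_hamming_closed_form(self):
        x = np.array([[1, 0, 0]])
        y = np.array([[0, 1, 0]])  # distance 2
        assert gaussian_gram(x, y, gamma=0.5)[0, 0] == pytest.approx(np.exp(-1.0))

    def test_small_gamma_limit(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, (5, 20))
        assert np.allclose(gaussian_gram(x, gamma=1e-12), 1.0, atol=1e-9)

    def test_column_mismatch_raises(self):
        with pytest.raises(ValueError, match="column"):
            gaussian_gram(np.zeros((2, 3)), np.zeros((2, 4)))

    @settings(max_examples=40, deadline=None)
    @given(
        x=arrays(np.int8, st.tuples(st.integers(2, 8), st.integers(1, 10)),
                 elements=st.integers(0, 1)),
        gamma=st.floats(0.01, 4.0),
    )
    def test_gram_is_psd_with_unit_diagonal(self, x, gamma):
        gram = gaussian_gram(x, gamma=gamma)
        assert np.allclose(np.diag(gram), 1.0)
        assert np.allclose(gram, gram.T)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8


class TestCombine:
    def _bundle(self, grams, weights):
        names = tuple(f"v{i}" for i in range(len(grams)))
        return KernelBundle(
            views=names,
            grams=dict(zip(names, grams)),
            weights=dict(zip(names, weights)),
            gamma=1.0,
        )

    def test_unit_weight_returns_gram(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, (4, 6))
        g = gaussian_gram(x, gamma=0.3)
        combined = combine(self._bundle([g, np.eye(4)], [1.0, 0.0]))
        assert np.array_equal(combined, g)

    def test_convexity_preserves_constant(self):
        combined = combine(self._bundle([np.ones((1, 1)), np.ones((1, 1))], [0.5, 0.5]))
        assert combined[0, 0] == pytest.approx(1.0)

    def test_entrywise_average(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        b = np.array([[1.0, 0.8], [0.8, 1.0]])
        combined = combine(self._bundle([a, b], [0.5, 0.5]))
        assert combined[0, 1] == pytest.approx(0.6)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            self._bundle([np.eye(2), np.eye(2)], [0.5, 0.2])


class TestEstimateWeights:
    def test_weights_nonnegative_and_sum_to_one(self, tiny_world):
        labels, annotations, homologs = tiny_world
        vocabs = build_vocabularies(annotations, labels.accessions(), homologs, 1)
        views = encode_views(labels.accessions(), annotations, homologs, 1, vocabs)
        weights = estimate_weights(views, labels, seed=0)
        assert all(w >= 0 for w in weights.values())
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_identical_views_share_weight_equally(self, tiny_world):
        labels, annotations, homologs = tiny_world
        vocabs = build_vocabularies(annotations, labels.accessions(), homologs, 1)
        views = encode_views(labels.accessions(), annotations, homologs, 1, vocabs)
        views.matrices["t_F"] = views.matrices["t_C"].copy()
        weights = estimate_weights(views, labels, active_views=("t_F", "t_C"), seed=0)
        assert weights["t_F"] == pytest.approx(weights["t_C"])
        assert weights["t_F"] == pytest.approx(0.5)

    def test_single_view_gets_full_weight(self, tiny_world):
        labels, annotations, homologs = tiny_world
        vocabs = build_vocabularies(annotations, labels.accessions(), homologs, 1)
        views = encode_views(labels.accessions(), annotations, homologs, 1, vocabs)
        weights = estimate_weights(views, labels, active_views=("t_C",), seed=0)
        assert weights == {"t_C": pytest.approx(1.0)}

    def test_signal_view_outweighs_noise_view(self, default_world):
        """A view carrying class signatures beats a pure-noise view.

        Majority vote over 5 inner seeds on the standard benchmark world
        with t_P replaced by label-independent random bits.
        """
        labels, annotations, homologs = default_world
        accessions = labels.accessions()[:300]
        labels300 = labels.subset(accessions)
        vocabs = build_vocabularies(annotations, accessions, homologs, 1)
        views = encode_views(accessions, annotations, homologs, 1, vocabs)
        rng = np.random.default_rng(7)
        views.matrices["t_P"] = rng.integers(
            0, 2, views.matrices["t_P"].shape
        ).astype(np.uint8)
        wins = 0
        for seed in range(5):
            weights = estimate_weights(
                views, labels300, active_views=("t_C", "t_P"), seed=seed
            )
            wins += int(weights["t_C"] > weights["t_P"])
        assert wins >= 3

    def test_missing_class_raises(self, tiny_world):
        labels, annotations, homologs = tiny_world
        accessions = labels.accessions()
        vocabs = build_vocabularies(annotations, accessions, homologs, 1)
        views = encode_views(accessions, annotations, homologs, 1, vocabs)
        ghost = LabelTable(
            dict(labels.labels), labels.location_catalog + ("Vacuole",)
        )
        with pytest.raises(ValueError, match="Vacuole"):
            estimate_weights(views, ghost, seed=0)

    def test_scores_match_brute_force_recount(self, micro_world):
        """Per-view scores equal an independent SE/MCC tally of pooled CV
        predictions (the score chain recomputed from scratch in the test)."""
        labels, annotations, homologs = micro_world
        accessions = labels.accessions()
        vocabs = build_vocabularies(annotations, accessions, homologs, 1)
        views = encode_views(accessions, annotations, homologs, 1, vocabs)
        _, scores = estimate_weights(
            views, labels, active_views=("t_C",), folds=2, seed=1, return_scores=True
        )
        # independent recomputation: same folds, same classifiers, but the
        # confusion matrix, SE and MCC tallied by hand
        gram = gaussian_gram(views.matrices["t_C"], gamma=0.125)
        folds = _stratify_folds(labels, accessions, 2, 1)
        row = {a: i for i, a in enumerate(accessions)}
        catalog = labels.location_catalog
        counts = {(t, p): 0 for t in catalog for p in catalog}
        for train_idx, val_idx in folds:
            train_accs = [accessions[i] for i in train_idx]
            inst = locative_expand(labels.subset(train_accs))
            rows = np.array([row[a] for a, _ in inst])
            model = train_ova(gram[np.ix_(rows, rows)], [l for _, l in inst],
                              C=8.0, seed=1)
            for i in val_idx:
                acc = accessions[i]
                probs = predict_proba(model, gram[np.ix_([row[acc]], rows)])[0]
                for t, p in rank_assign_locative(probs, model.classes,
                                                 labels.labels[acc]):
                    counts[(t, p)] += 1
        total = sum(counts.values())
        per_class = []
        for c in catalog:
            tp = counts[(c, c)]
            fn = sum(counts[(c, p)] for p in catalog) - tp
            fp = sum(counts[(t, c)] for t in catalog) - tp
            tn = total - tp - fn - fp
            se = tp / (tp + fn) if tp + fn else 0.0
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fp * fn) / denom**0.5 if denom else 0.0
            per_class.append((se + max(mcc, 0.0)) / 2)
        assert scores["t_C"] == pytest.approx(np.mean(per_class))


class TestApplyScenario:
    def _views(self, seed=0, n=4, m=2, u=6):
        rng = np.random.default_rng(seed)
        train = FeatureViews(
            tuple(f"tr{i}" for i in range(n)),
            {v: rng.integers(0, 2, (n, u)).astype(np.uint8) for v in VIEW_NAMES},
        )
        test = FeatureViews(
            tuple(f"te{i}" for i in range(m)),
            {v: rng.integers(0, 2, (m, u)).astype(np.uint8) for v in VIEW_NAMES},
        )
        return train, test

    def test_moderate_equals_optimistic_when_homolog_matches_target(self):
        train, test = self._views()
        for aspect in "FCP":
            test.matrices[f"h_{aspect}"] = test.matrices[f"t_{aspect}"]
        w = {v: 1 / 6 for v in VIEW_NAMES}
        _, opt = apply_scenario(train, test, "optimistic", 0.5, w)
        _, mod = apply_scenario(train, test, "moderate", 0.5, w)
        assert np.allclose(opt, mod)

    def test_pessimistic_uses_exactly_homolog_views(self):
        train, test = self._views()
        with pytest.raises(ValueError, match="h_"):
            apply_scenario(train, test, "pessimistic", 0.5, {v: 1 / 6 for v in VIEW_NAMES})
        w3 = {v: 1 / 3 for v in ("h_F", "h_C", "h_P")}
        train_gram, cross = apply_scenario(train, test, "pessimistic", 0.5, w3)
        expected = sum(
            gaussian_gram(train.matrices[v], gamma=0.5) / 3 for v in w3
        )
        assert np.allclose(train_gram, expected)

    def test_moderate_zero_homolog_vector_closed_form(self):
        train, test = self._views()
        for v in VIEW_NAMES:
            test.matrices[v] = np.zeros_like(test.matrices[v])
        gamma = 0.25
        w = {v: (1.0 if v == "t_C" else 0.0) for v in VIEW_NAMES}
        _, cross = apply_scenario(train, test, "moderate", gamma, w)
        popcount = train.matrices["t_C"].sum(axis=1)
        assert np.allclose(cross[0], np.exp(-gamma * popcount))

    def test_unknown_scenario_raises(self):
        train, test = self._views()
        with pytest.raises(ValueError, match="scenario"):
            apply_scenario(train, test, "hopeful", 0.5, {})

    def test_combined_train_gram_is_psd(self, tiny_world):
        labels, annotations, homologs = tiny_world
        vocabs = build_vocabularies(annotations, labels.accessions(), homologs, 1)
        views = encode_views(labels.accessions(), annotations, homologs, 1, vocabs)
        w = {v: 1 / 6 for v in VIEW_NAMES}
        gram, _ = apply_scenario(views, None, "optimistic", 0.125, w)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8
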