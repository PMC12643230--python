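"""Pair generation, RankSVM training/prediction, CV, RF baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retorder as ro
from retorder.ranking import (
    DEFAULT_C_GRID,
    PairSample,
    cross_validate,
    make_pairs,
    pairwise_accuracy,
    train_ranksvm,
)


def _items_1d(rts, feature=None):
    """(id, 1-D pcf, rt) items; feature defaults to the RT itself."""
    vals = rts if feature is None else feature
    return [
        (f"m{i}", np.array([float(v)]), float(rt))
        for i, (v, rt) in enumerate(zip(vals, rts))
    ]


class TestMakePairs:
    def test_three_compounds_exhaustive(self):
        ps = make_pairs(_items_1d([1.0, 2.0, 3.0]))
        assert len(ps) == 3 and ps.n_ties == 0
        for p in ps:
            a, b = int(p.ids[0][1:]), int(p.ids[1][1:])
            assert p.label == (1 if a < b else -1)  # rt increases with index

    def test_equal_rts_yield_tie_not_pair(self):
        ps = make_pairs(_items_1d([2.0, 2.0]))
        assert len(ps) == 0 and ps.n_ties == 1

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_pair_count_matches_brute_force(self, rts):
        items = _items_1d([float(r) for r in rts])
        ps = make_pairs(items)
        n = len(rts)
        ties = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if rts[i] == rts[j]
        )
        assert len(ps) == n * (n - 1) // 2 - ties
        assert ps.n_ties == ties

    def test_canonical_orientation_by_id(self):
        ps = make_pairs(_items_1d([3.0, 1.0]))
        (pair,) = ps.pairs
        assert pair.ids == ("m0", "m1")
        assert pair.label == -1  # m0 elutes after m1

    def test_missing_rt_names_compound(self):
        items = [("a", np.array([1.0]), 1.0), ("b", np.array([2.0]), None)]
        with pytest.raises(ValueError, match="'b'"):
            make_pairs(items)

    def test_min_delta_rt_filters_close_pairs(self):
        ps = make_pairs(_items_1d([1.0, 1.05, 3.0]), min_delta_rt=0.1)
        assert len(ps) == 2 and ps.n_ties == 1


class TestTrainRankSVM:
    def test_monotone_feature_separates_with_positive_weight(self):
        # 1-D PCF equal to the RT: earlier compound has smaller feature, so
        # label +1 pairs have negative delta and the weight must be negative
        # under the "+1 = a before b, score = w·(x_a − x_b) ≥ 0" convention.
        items = _items_1d([1.0, 2.0, 3.0, 4.0, 5.0])
        model = train_ranksvm(list(make_pairs(items)), C=1.0)
        assert pairwise_accuracy(model, list(make_pairs(items))) == 1.0
        assert model.weights[0] < 0

    def test_negated_feature_flips_weight(self):
        rts = [1.0, 2.0, 3.0, 4.0, 5.0]
        items = _items_1d(rts, feature=[-r for r in rts])
        model = train_ranksvm(list(make_pairs(items)), C=1.0)
        assert pairwise_accuracy(model, list(make_pairs(items))) == 1.0
        assert model.weights[0] > 0

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="no training pairs"):
            train_ranksvm([], C=1.0)

    @pytest.mark.parametrize("C", [0.0, -1.0])
    def test_nonpositive_C_rejected(self, C):
        ps = make_pairs(_items_1d([1.0, 2.0]))
        with pytest.raises(ValueError, match="C must be positive"):
            train_ranksvm(list(ps), C=C)

    def test_convention_independence(self):
        """Swapping both compounds of each pair and flipping labels gives the
        identical model: only label·delta enters the objective."""
        rng = np.random.default_rng(0)
        deltas = rng.normal(size=(30, 4))
        labels = rng.choice([-1, 1], size=30)
        pairs = [
            PairSample(delta=d, label=int(l), ids=("a", "b"))
            for d, l in zip(deltas, labels)
        ]
        flipped = [
            PairSample(delta=-d, label=-int(l), ids=("b", "a"))
            for d, l in zip(deltas, labels)
        ]
        w1 = train_ranksvm(pairs, C=0.5).weights
        w2 = train_ranksvm(flipped, C=0.5).weights
        assert np.allclose(w1, w2)

    def test_monotone_rt_relabeling_leaves_model_unchanged(self):
        rts = [0.5, 1.2, 2.0, 3.3, 4.1]
        items_a = _items_1d(rts, feature=[1, 5, 2, 4, 3])
        items_b = _items_1d([np.exp(r) for r in rts], feature=[1, 5, 2, 4, 3])
        wa = train_ranksvm(list(make_pairs(items_a)), C=1.0).weights
        wb = train_ranksvm(list(make_pairs(items_b)), C=1.0).weights
        assert np.allclose(wa, wb)

    def test_rbf_model_is_antisymmetric(self):
        rng = np.random.default_rng(1)
        items = [
            (f"m{i}", rng.normal(size=3), float(i)) for i in range(8)
        ]
        model = train_ranksvm(list(make_pairs(items)), C=1.0, kernel="rbf")
        for _ in range(5):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert model.predict_order(a, b) == -model.predict_order(b, a) or (
                model.decision(a - b) == 0
            )

    def test_unknown_kernel_rejected(self):
        ps = make_pairs(_items_1d([1.0, 2.0]))
        with pytest.raises(ValueError, match="kernel"):
            train_ranksvm(list(ps), kernel="poly")


class TestPredictOrder:
    @pytest.fixture()
    def model(self):
        items = _items_1d([1.0, 2.0, 3.0, 4.0])
        return train_ranksvm(list(make_pairs(items)), C=1.0)

    def test_identical_vectors_tie_break_to_before(self, model):
        x = np.array([2.0])
        assert model.predict_order(x, x) == 1

    def test_antisymmetry_on_random_vectors(self, model, rng):
        for _ in range(20):
            a, b = rng.normal(size=1), rng.normal(size=1)
            if model.decision(a - b) != 0:
                assert model.predict_order(a, b) == -model.predict_order(b, a)

    def test_agrees_with_dot_product_oracle(self, model, rng):
        for _ in range(20):
            a, b = rng.normal(size=1), rng.normal(size=1)
            expected = 1 if float(model.weights @ (a - b)) >= 0 else -1
            assert ro.predict_order(model, a, b) == expected

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="dimension"):
            model.predict_order(np.ones(3), np.ones(3))


class TestCrossValidate:
    def test_identical_subsets_give_identical_fold_accuracies(self):
        items = _items_1d([1.0, 2.0, 3.0, 4.0])
        ps = make_pairs(items)
        cv = cross_validate([ps, ps, ps], C_grid=[0.1, 1.0])
        for _, group in cv.table.groupby("C"):
            assert group["accuracy"].nunique() == 1

    def test_contradictory_pairs_score_at_chance(self, rng):
        deltas = rng.normal(size=(40, 3))
        subset_a = [
            PairSample(delta=d, label=1, ids=(f"a{i}", f"b{i}"))
            for i, d in enumerate(deltas)
        ]
        subset_b = [
            PairSample(delta=d, label=-1, ids=(f"c{i}", f"d{i}"))
            for i, d in enumerate(deltas)
        ]
        cv = cross_validate([subset_a, subset_b], C_grid=[1.0])
        # each fold tests the exact mirror of its training data
        assert cv.table["accuracy"].mean() == pytest.approx(0.5, abs=0.2)

    def test_table_enumerates_grid_by_folds(self):
        items = _items_1d([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        subsets = [
            make_pairs(items[:3]), make_pairs(items[3:]),
        ]
        grid = [0.01, 0.1, 1.0]
        cv = cross_validate(subsets, C_grid=grid)
        assert len(cv.table) == len(grid) * len(subsets)
        assert cv.best_C in grid

    def test_fewer_than_two_subsets_rejected(self):
        ps = make_pairs(_items_1d([1.0, 2.0]))
        with pytest.raises(ValueError, match="at least 2"):
            cross_validate([ps])

    def test_separable_data_reaches_perfect_heldout_accuracy(self):
        rts = np.linspace(1, 10, 12)
        items = _items_1d(rts)
        subsets = [make_pairs(items[0::2]), make_pairs(items[1::2])]
        cv = cross_validate(subsets, C_grid=list(DEFAULT_C_GRID))
        assert cv.best_mean_accuracy == 1.0


class TestRFBaseline:
    def test_memorizes_duplicated_training_compounds(self, rng):
        # Replicating each compound makes every bootstrap sample contain it,
        # so deep trees reproduce its RT almost exactly.
        X = rng.normal(size=(30, 4))
        rt = rng.uniform(1, 10, size=30)
        rf = ro.rf_baseline(np.repeat(X, 10, axis=0), np.repeat(rt, 10),
                            n_trees=200, seed=0)
        assert rf.predict_rt(X) == pytest.approx(rt, abs=0.3)

    def test_constant_rt_training_gives_deterministic_tie_break(self, rng):
        X = rng.normal(size=(20, 3))
        rf = ro.rf_baseline(X, np.full(20, 5.0), n_trees=50, seed=0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert rf.predict_order(a, b) == 1  # equal predictions → "a before b"

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ro.rf_baseline(np.empty((0, 3)), [])

    def test_shared_harness_scores_rf_and_svm_identically(self, rng):
        """pairwise_accuracy_items must agree with a per-pair predict_order
        loop for both model families."""
        items = [(f"m{i}", rng.normal(size=3), float(i)) for i in range(10)]
        X = np.vstack([x for _, x, _ in items])
        rf = ro.rf_baseline(X, [rt for _, _, rt in items], n_trees=50, seed=0)
        svm = train_ranksvm(list(make_pairs(items)), C=0.1)
        for model in (rf, svm):
            fast = ro.pairwise_accuracy_items(model, items)
            slow_hits, total = 0, 0
            ordered = sorted(items, key=lambda t: t[0])
            for i in range(len(ordered)):
                for j in range(i + 1, len(ordered)):
                    truth = 1 if ordered[i][2] < ordered[j][2] else -1
                    total += 1
                    if model.predict_order(ordered[i][1], ordered[j][1]) == truth:
                        slow_hits += 1
            assert fast == pytest.approx(slow_hits / total)
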