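import math

import numpy as np
import pytest

import hlabind as hb
from hlabind.selection import _discretize_matrix


def oracle_mi(x, y):
    """Term-by-term plug-in mutual information (bits), explicit loops."""
    x, y = list(x), list(y)
    n = len(x)
    total = 0.0
    for xv in set(x):
        for yv in set(y):
            pxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv) / n
            if pxy == 0:
                continue
            px = x.count(xv) / n
            py = y.count(yv) / n
            total += pxy * math.log2(pxy / (px * py))
    return total


def oracle_mrmr(X, y, mi=oracle_mi):
    """Exhaustive per-step arg-max greedy mRMR on discretized columns."""
    S = _discretize_matrix(np.asarray(X, dtype=float))
    D = S.shape[1]
    rel = [mi(S[:, j], y) for j in range(D)]
    selected = []
    while len(selected) < D:
        best, best_crit = None, -np.inf
        for j in range(D):
            if j in selected:
                continue
            red = (
                sum(mi(S[:, j], S[:, s]) for s in selected) / len(selected)
                if selected
                else 0.0
            )
            crit = rel[j] - red
            if crit > best_crit:  # strict: ties keep the smaller index
                best, best_crit = j, crit
        selected.append(best)
    return selected


class TestDiscretize:
    def test_constant_vector_single_state(self):
        assert np.all(hb.discretize([3.0] * 7) == 1)

    def test_three_point_spread(self):
        # mean 0, sd ~8.16: cuts at -4.08 / +4.08 separate the three values
        assert list(hb.discretize([-10.0, 0.0, 10.0])) == [0, 1, 2]

    def test_normal_sample_occupancy(self):
        rng = np.random.default_rng(5)
        s = hb.discretize(rng.standard_normal(10_000))
        occ = np.bincount(s, minlength=3) / s.size
        # P(|Z| <= 0.5) ~ 0.383; each state well populated
        assert np.all(occ >= 0.10)

    def test_empty_is_domain_error(self):
        with pytest.raises(ValueError):
            hb.discretize([])


class TestMutualInformation:
    def test_identical_fair_coin_is_one_bit(self):
        x = np.array([0, 1] * 8)
        assert hb.mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_product_joint_is_zero(self):
        # exact product joint: every (x, y) cell equally populated
        x = np.repeat([0, 1], 4)
        y = np.tile([0, 1], 4)
        assert hb.mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_small_contingency_table_term_by_term(self):
        # joint counts [[2,1],[1,2]], n=6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert hb.mutual_information(x, y) == pytest.approx(oracle_mi(x, y), abs=1e-12)

    def test_symmetry_and_self_information(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 3, size=40)
            y = rng.integers(0, 2, size=40)
            assert hb.mutual_information(x, y) == pytest.approx(
                hb.mutual_information(y, x), abs=1e-12
            )
            # MI(x, x) equals the empirical entropy of x
            p = np.bincount(x) / x.size
            ent = -sum(pi * math.log2(pi) for pi in p if pi > 0)
            assert hb.mutual_information(x, x) == pytest.approx(ent, abs=1e-12)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            hb.mutual_information([0, 1], [0, 1, 0])


class TestMaxRel:
    def test_informative_column_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        X = np.column_stack([y.astype(float), rng.random(200)])
        assert hb.maxrel_rank(X, y).order[0] == 0

    def test_duplicated_informative_above_noise(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=300)
        X = np.column_stack([rng.random(300), y.astype(float), y.astype(float)])
        order = list(hb.maxrel_rank(X, y).order)
        assert set(order[:2]) == {1, 2}

    def test_matches_per_column_oracle(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=60)
        X = rng.random((60, 5))
        ranked = hb.maxrel_rank(X, y)
        S = _discretize_matrix(X)
        scores = [oracle_mi(S[:, j], y) for j in range(5)]
        expected = sorted(range(5), key=lambda j: (-scores[j], j))
        assert list(ranked.order) == expected

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            hb.maxrel_rank(np.random.default_rng(0).random((9, 2)), [0, 1, 2] * 3)


class TestMRMR:
    def test_first_pick_is_maxrel_top(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=100)
        X = rng.random((100, 6))
        X[:, 4] += y  # make one clearly relevant
        assert hb.mrmr_rank(X, y).order[0] == hb.maxrel_rank(X, y).order[0] == 4

    def test_duplicate_column_demoted(self):
        # A and B identical noisy copies of y; C weaker but non-redundant
        rng = np.random.default_rng(8)
        n = 600
        y = rng.integers(0, 2, size=n)
        a = np.where(rng.random(n) < 0.9, y, 1 - y).astype(float)
        c = np.where(rng.random(n) < 0.75, y, 1 - y).astype(float)
        X = np.column_stack([a, a.copy(), c])
        assert list(hb.maxrel_rank(X, y).order) == [0, 1, 2]
        assert list(hb.mrmr_rank(X, y).order) == [0, 2, 1]

    def test_greedy_matches_exhaustive_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 61))
            D = int(rng.integers(3, 7))
            y = rng.integers(0, 2, size=n)
            while len(np.unique(y)) < 2:
                y = rng.integers(0, 2, size=n)
            X = rng.random((n, D))
            X[:, 0] += 0.5 * y
            assert list(hb.mrmr_rank(X, y).order) == oracle_mrmr(X, y), f"seed {seed}"

    def test_orders_are_permutations_sharing_first_element(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=80)
        X = rng.random((80, 12))
        mr = hb.maxrel_rank(X, y)
        mm = hb.mrmr_rank(X, y)
        assert sorted(mr.order) == sorted(mm.order) == list(range(12))
        assert mr.order[0] == mm.order[0]

    def test_truncated_ranking_is_prefix_of_full(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=100)
        X = rng.random((100, 10))
        full = hb.mrmr_rank(X, y)
        part = hb.mrmr_rank(X, y, k=4)
        assert not part.complete
        assert list(part.order) == list(full.order[:4])


class TestIFS:
    def test_nested_sets(self):
        ranked = hb.RankedFeatureList("mRMR", np.array([3, 0, 2, 1, 4]), np.zeros(5), 5)
        sets = hb.ifs_sets(ranked)
        assert [len(s) for s in sets] == [1, 2, 3, 4, 5]
        assert list(sets[1]) == [3, 0]
        for a, b in zip(sets, sets[1:]):
            assert set(a) < set(b)

    def test_select_optimal_tie_smallest_size(self):
        import pandas as pd

        curve = pd.DataFrame(
            {"size": [1, 2, 3], "SN": 0.0, "SP": 0.0, "ACC": 0.0, "MCC": [0.1, 0.3, 0.25]}
        )
        assert hb.select_optimal(curve) == (2, 0.3)
        curve["MCC"] = 0.2
        assert hb.select_optimal(curve) == (1, 0.2)
        curve["MCC"] = [0.0, 0.1, 0.4]
        assert hb.select_optimal(curve) == (3, 0.4)

    def test_perfectly_separable_optimum_at_size_one(self):
        rng = np.random.default_rng(0)
        n = 80
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y * 10.0, rng.random(n), rng.random(n)])
        ranked = hb.mrmr_rank(X, y)
        assert ranked.order[0] == 0
        res = hb.evaluate_ifs(X, y, ranked, k=4, seed=0)
        assert res.optimal_size == 1
        assert res.curve["MCC"].iloc[0] == pytest.approx(1.0)

    def test_curve_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, size=100)
        X = rng.random((100, 6))
        ranked = hb.mrmr_rank(X, y)
        a = hb.evaluate_ifs(X, y, ranked, k=5, seed=3)
        b = hb.evaluate_ifs(X, y, ranked, k=5, seed=3)
        assert a.curve.equals(b.curve)

    def test_fast_nna_path_equals_generic_refit(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, size=60)
        X = rng.random((60, 5))
        ranked = hb.mrmr_rank(X, y)
        fast = hb.evaluate_ifs(X, y, ranked, estimator=hb.NearestNeighborClassifier(), k=4, seed=1)

        class SlowNNA(hb.NearestNeighborClassifier):
            pass  # subclass bypasses the incremental-distance fast path

        slow = hb.evaluate_ifs(X, y, ranked, estimator=SlowNNA(), k=4, seed=1)
        assert fast.curve.equals(slow.curve)

    def test_fold_without_both_classes_suggests_smaller_k(self):
        y = np.array([1] * 3 + [0] * 50)
        X = np.random.default_rng(1).random((53, 4))
        ranked = hb.mrmr_rank(X, y)
        with pytest.raises(ValueError, match="smaller k"):
            hb.evaluate_ifs(X, y, ranked, k=10, seed=0)


class TestEstimators:
    def test_mrmr_ranker_transform_selects_top_k(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=120)
        X = rng.random((120, 8))
        X[:, 5] += y
        r = hb.MRMRRanker(k=3).fit(X, y)
        assert r.ranking_.order[0] == 5
        assert r.transform(X).shape == (120, 3)

    def test_incremental_selector_support_matches_optimum(self):
        rng = np.random.default_rng(4)
        n = 100
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y * 5.0, rng.random((n, 4))])
        sel = hb.IncrementalFeatureSelector(cv=5, random_state=0).fit(X, y)
        assert sel.optimal_size_ == int(sel.support_.sum())
        assert sel.transform(X).shape == (n, sel.optimal_size_)
        assert sel.curve_.shape[0] == X.shape[1]
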